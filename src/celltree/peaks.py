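"""Reading, validating and filtering ChIP-Seq peak lists.

Peaks are consumed as called intervals (ENCODE narrowPeak / broadPeak /
plain BED); peak calling itself is upstream of this package.  All
coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PeakInterval",
    "PeakLibrary",
    "ManifestEntry",
    "LibraryManifest",
    "PeakFileError",
    "read_peak_file",
    "write_peak_file",
    "filter_by_significance",
    "load_manifest",
    "write_manifest",
    "DIALECTS",
]


class PeakFileError(ValueError):
    """Raised for malformed peak files or manifests."""


@dataclass(frozen=True)
class PeakInterval:
    """One called peak: a half-open genomic interval, optionally scored.

    ``neg_log_p`` is the peak caller's -log10 p-value (column 8 of
    narrowPeak/broadPeak); absent for plain BED3 input.
    """

    chrom: str
    start: int
    end: int
    neg_log_p: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise PeakFileError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise PeakFileError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.neg_log_p is not None and self.neg_log_p < 0:
            raise PeakFileError(f"negative -log10 p-value {self.neg_log_p}")

    @property
    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlaps(self, other: "PeakInterval") -> bool:
        """Strict half-open overlap: touching intervals do not overlap."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class PeakLibrary:
    """One ChIP-Seq library: identity metadata plus its sorted peaks."""

    library_id: str
    cell_type: str
    replicate: int
    group: str
    peaks: tuple[PeakInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate index must be >= 1, got {self.replicate}")
        object.__setattr__(self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.sort_key)))

    def __len__(self) -> int:
        return len(self.peaks)

    def validate(self) -> list[str]:
        """Report (but do not forbid) overlapping peaks within the library."""
        issues = []
        for a, b in zip(self.peaks, self.peaks[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                issues.append(
                    f"{self.library_id}: overlapping peaks "
                    f"{a.chrom}:{a.start}-{a.end} and {b.chrom}:{b.start}-{b.end}"
                )
        return issues


@dataclass(frozen=True)
class ManifestEntry:
    path: str | None
    library_id: str
    cell_type: str
    replicate: int
    group: str


@dataclass(frozen=True)
class LibraryManifest:
    """Binds peak files to library identity (cell type, replicate, group)."""

    entries: tuple[ManifestEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.library_id for e in self.entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PeakFileError(f"duplicate library_id(s) in manifest: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.entries)

    def cell_type_of(self, library_id: str) -> str:
        return self._by_id()[library_id].cell_type

    def group_of(self, library_id: str) -> str:
        return self._by_id()[library_id].group

    def _by_id(self) -> dict[str, ManifestEntry]:
        return {e.library_id: e for e in self.entries}

    def replicates_of(self, cell_type: str) -> list[str]:
        return [e.library_id for e in self.entries if e.cell_type == cell_type]

    def cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.cell_type, None)
        return list(seen)

    def load_libraries(self, dialect: str = "narrowPeak",
                       pvalue_column: int | None = None) -> list[PeakLibrary]:
        """Read every entry's peak file into a :class:`PeakLibrary`."""
        libs = []
        for e in self.entries:
            if e.path is None:
                raise PeakFileError(f"manifest entry {e.library_id} has no file path")
            peaks = read_peak_file(e.path, dialect=dialect, pvalue_column=pvalue_column)
            libs.append(PeakLibrary(e.library_id, e.cell_type, e.replicate, e.group, peaks))
        return libs


# dialect -> (minimum column count, 0-based index of the -log10 p column or None)
DIALECTS: dict[str, tuple[int, int | None]] = {
    "narrowPeak": (10, 7),
    "broadPeak": (9, 7),
    "bed3": (3, None),
    "bed+p": (4, None),  # p-value column supplied by the caller
}


def read_peak_file(path: str | os.PathLike, dialect: str = "narrowPeak",
                   pvalue_column: int | None = None) -> tuple[PeakInterval, ...]:
    """Parse a peak file into sorted :class:`PeakInterval` records.

    Parameters
    ----------
    path
        Peak file; lines starting with ``track``, ``browser`` or ``#`` are
        skipped.
    dialect
        One of ``narrowPeak``, ``broadPeak``, ``bed3``, ``bed+p``.  The two
        ENCODE dialects read the -log10 p-value from column 8; ``bed+p``
        reads it from the 1-based ``pvalue_column``.
    """
    if dialect not in DIALECTS:
        raise PeakFileError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    min_cols, p_idx = DIALECTS[dialect]
    if dialect == "bed+p":
        if pvalue_column is None:
            raise PeakFileError("dialect 'bed+p' requires pvalue_column (1-based)")
        p_idx = pvalue_column - 1
        min_cols = max(min_cols, pvalue_column)

    peaks: list[PeakInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise PeakFileError(
                    f"{path}:{lineno}: expected >= {min_cols} tab-separated "
                    f"fields for dialect {dialect!r}, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PeakFileError(f"{path}:{lineno}: non-integer coordinates") from exc
            neg_log_p = None
            if p_idx is not None:
                try:
                    neg_log_p = float(fields[p_idx])
                except ValueError as exc:
                    raise PeakFileError(
                        f"{path}:{lineno}: column {p_idx + 1} is not a number"
                    ) from exc
            try:
                peaks.append(PeakInterval(fields[0], start, end, neg_log_p))
            except PeakFileError as exc:
                raise PeakFileError(f"{path}:{lineno}: {exc}") from exc
    peaks.sort(key=lambda p: p.sort_key)
    return tuple(peaks)


def write_peak_file(peaks: Iterable[PeakInterval], path: str | os.PathLike,
                    dialect: str = "narrowPeak") -> None:
    """Write peaks in narrowPeak (BED6+4) or BED3 layout."""
    with open(path, "w") as fh:
        for i, p in enumerate(sorted(peaks, key=lambda p: p.sort_key)):
            if dialect == "bed3":
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
            else:
                nlp = p.neg_log_p if p.neg_log_p is not None else -1
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t0\t.\t0\t{nlp:g}\t-1\t-1\n"
                )


def filter_by_significance(library: PeakLibrary, threshold: float) -> PeakLibrary:
    """Keep only peaks whose -log10 p-value is >= ``threshold`` (inclusive).

    ENCODE peak lists carry a p-value per peak; discarding weak peaks is the
    standard "top peaks" noise filter (threshold 10 in typical use).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    missing = [p for p in library.peaks if p.neg_log_p is None]
    if missing:
        raise PeakFileError(
            f"{library.library_id}: {len(missing)} peak(s) lack a -log10 p-value; "
            "re-read the file with a dialect that has a p-value column "
            "(narrowPeak, broadPeak or bed+p)"
        )
    kept = tuple(p for p in library.peaks if p.neg_log_p >= threshold)
    return replace(library, peaks=kept)


_MANIFEST_COLUMNS = ("path", "library_id", "cell_type", "replicate", "group")


def load_manifest(path: str | os.PathLike, check_files: bool = True) -> LibraryManifest:
    """Load the tab-separated library manifest.

    Expected header: ``path  library_id  cell_type  replicate  group``.
    Relative peak-file paths are resolved against the manifest's directory.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        missing = [c for c in _MANIFEST_COLUMNS if c not in header]
        if missing:
            raise PeakFileError(f"{path}: manifest header missing column(s) {missing}")
        idx = {c: header.index(c) for c in _MANIFEST_COLUMNS}
        entries = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                raise PeakFileError(f"{path}:{lineno}: short row")
            try:
                rep = int(fields[idx["replicate"]])
            except ValueError as exc:
                raise PeakFileError(f"{path}:{lineno}: replicate is not an integer") from exc
            peak_path = Path(fields[idx["path"]])
            if not peak_path.is_absolute():
                peak_path = path.parent / peak_path
            if check_files and not peak_path.exists():
                raise PeakFileError(f"{path}:{lineno}: peak file not found: {peak_path}")
            entries.append(ManifestEntry(
                str(peak_path),
                fields[idx["library_id"]],
                fields[idx["cell_type"]],
                rep,
                fields[idx["group"]],
            ))
    return LibraryManifest(tuple(entries))


def write_manifest(manifest: LibraryManifest, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_MANIFEST_COLUMNS) + "\n")
        for e in manifest.entries:
            fh.write(f"{e.path}\t{e.library_id}\t{e.cell_type}\t{e.replicate}\t{e.group}\n")
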