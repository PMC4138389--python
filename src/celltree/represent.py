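"""Binary and profile data representations of peak libraries.

Two ways of turning peak lists into a libraries x features 0/1 matrix:

* **windowing** — fixed-size genome bins, coded 1 when any peak of the
  library overlaps the bin; each library is coded independently.
* **overlap** — one column per *interesting region*, a connected component
  of the interval graph over all peaks of all libraries; coded jointly, so
  every column has at least one 1 by construction.

A **profile** matrix averages replicate rows per cell type, giving values
in [0, 1] that are multiples of 1/r for r replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .peaks import LibraryManifest, PeakInterval, PeakLibrary

__all__ = [
    "FeatureColumn",
    "BinaryMatrix",
    "ProfileMatrix",
    "build_windowing_matrix",
    "find_interesting_regions",
    "build_overlap_matrix",
    "build_profile_matrix",
    "mask_near_constant_columns",
    "consensus_by_cell_type",
    "write_regions_bed",
]


@dataclass(frozen=True)
class FeatureColumn:
    """A matrix column's genomic footprint: a bin or an interesting region."""

    kind: str  # "bin" | "region"
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in ("bin", "region"):
            raise ValueError(f"kind must be 'bin' or 'region', got {self.kind!r}")
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    @property
    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def id(self, bin_size: int | None = None) -> str:
        if self.kind == "bin" and bin_size:
            return f"bin:{self.chrom}:{self.start // bin_size}"
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class BinaryMatrix:
    """Libraries x genomic-features 0/1 matrix."""

    row_labels: list[str]
    columns: list[FeatureColumn]
    values: np.ndarray  # shape (n_rows, n_cols), dtype uint8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.row_labels), len(self.columns)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_labels)} rows x {len(self.columns)} columns"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, label: str) -> np.ndarray:
        return self.values[self.row_labels.index(label)]

    def subset_rows(self, labels: Sequence[str]) -> "BinaryMatrix":
        idx = [self.row_labels.index(l) for l in labels]
        return BinaryMatrix(list(labels), list(self.columns), self.values[idx])

    def subset_columns(self, indices: Sequence[int]) -> "BinaryMatrix":
        idx = list(indices)
        return BinaryMatrix(
            list(self.row_labels), [self.columns[i] for i in idx], self.values[:, idx]
        )

    def to_tsv(self, path: str) -> None:
        """Feature-per-line TSV: first column the feature id, then libraries."""
        with open(path, "w") as fh:
            fh.write("feature\t" + "\t".join(self.row_labels) + "\n")
            for j, col in enumerate(self.columns):
                vals = "\t".join(str(int(v)) for v in self.values[:, j])
                fh.write(f"{col.id()}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path: str, kind: str = "region") -> "BinaryMatrix":
        with open(path) as fh:
            row_labels = fh.readline().rstrip("\n").split("\t")[1:]
            columns, rows = [], []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                chrom, span = fields[0].rsplit(":", 1)
                start, end = span.split("-")
                columns.append(FeatureColumn(kind, chrom, int(start), int(end)))
                rows.append([int(v) for v in fields[1:]])
        values = np.array(rows, dtype=np.uint8).T if rows else np.zeros((len(row_labels), 0))
        return cls(row_labels, columns, values)


@dataclass
class ProfileMatrix:
    """Cell types x features matrix of replicate-averaged presence values."""

    row_labels: list[str]  # cell types
    columns: list[FeatureColumn]
    values: np.ndarray  # floats in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.columns)):
            raise ValueError("profile shape mismatch")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("profile values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _sorted_columns(cols: Iterable[FeatureColumn]) -> list[FeatureColumn]:
    return sorted(cols, key=lambda c: c.sort_key)


def build_windowing_matrix(
    libraries: Sequence[PeakLibrary],
    bin_size: int = 200,
    chrom_sizes: Mapping[str, int] | None = None,
) -> BinaryMatrix:
    """Fixed-bin 0/1 coding of each library, independent of the others.

    A bin is coded 1 for a library when any of its peaks overlaps the bin
    interval ``[k*bin_size, (k+1)*bin_size)``; a peak straddling a boundary
    lights up every bin it touches.  Bins with no peak in any library are
    not materialised (they cannot affect Hamming distances).  The 200 bp
    default approximates one nucleosome plus linker.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if not libraries:
        raise ValueError("need at least one library")
    hits: list[set[tuple[str, int]]] = []
    for lib in libraries:
        lib_hits: set[tuple[str, int]] = set()
        for p in lib.peaks:
            if chrom_sizes is not None and p.chrom in chrom_sizes and p.end > chrom_sizes[p.chrom]:
                raise ValueError(
                    f"{lib.library_id}: peak {p.chrom}:{p.start}-{p.end} extends "
                    f"beyond declared chromosome length {chrom_sizes[p.chrom]}"
                )
            for k in range(p.start // bin_size, (p.end - 1) // bin_size + 1):
                lib_hits.add((p.chrom, k))
        hits.append(lib_hits)
    universe = sorted(set().union(*hits))
    columns = []
    for chrom, k in universe:
        end = (k + 1) * bin_size
        if chrom_sizes is not None and chrom in chrom_sizes:
            end = min(end, chrom_sizes[chrom])
        columns.append(FeatureColumn("bin", chrom, k * bin_size, end))
    col_index = {key: j for j, key in enumerate(universe)}
    values = np.zeros((len(libraries), len(universe)), dtype=np.uint8)
    for i, lib_hits in enumerate(hits):
        for key in lib_hits:
            values[i, col_index[key]] = 1
    return BinaryMatrix([l.library_id for l in libraries], columns, values)


def find_interesting_regions(libraries: Sequence[PeakLibrary]) -> list[FeatureColumn]:
    """Connected components of the interval graph over all peaks of all libraries.

    Single left-to-right sweep per chromosome over the pooled sorted peaks:
    a region extends while the next peak starts before the running maximum
    right endpoint (half-open intervals that merely touch do not overlap).
    Linear in the total number of peaks after sorting; the result is unique
    for a given input.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for lib in libraries:
        for p in lib.peaks:
            by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    regions: list[FeatureColumn] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        a, b = ivs[0]
        for s, e in ivs[1:]:
            if s < b:  # strict overlap under the half-open convention
                b = max(b, e)
            else:
                regions.append(FeatureColumn("region", chrom, a, b))
                a, b = s, e
        regions.append(FeatureColumn("region", chrom, a, b))
    return regions


def build_overlap_matrix(
    libraries: Sequence[PeakLibrary],
) -> tuple[list[FeatureColumn], BinaryMatrix]:
    """Code each library against the shared interesting regions.

    Entry (n, z) is 1 iff library n has at least one peak intersecting
    interesting region z.  Every column has at least one 1 because regions
    are built from the pooled peaks.
    """
    regions = find_interesting_regions(libraries)
    region_index: dict[str, list[tuple[int, int, int]]] = {}
    for j, r in enumerate(regions):
        region_index.setdefault(r.chrom, []).append((r.start, r.end, j))
    values = np.zeros((len(libraries), len(regions)), dtype=np.uint8)
    for i, lib in enumerate(libraries):
        for chrom, chrom_regions in region_index.items():
            peaks = [(p.start, p.end) for p in lib.peaks if p.chrom == chrom]
            ri = 0
            for s, e in peaks:  # both lists sorted: two-pointer sweep
                while ri < len(chrom_regions) and chrom_regions[ri][1] <= s:
                    ri += 1
                if ri < len(chrom_regions) and chrom_regions[ri][0] < e:
                    values[i, chrom_regions[ri][2]] = 1
    return regions, BinaryMatrix([l.library_id for l in libraries], list(regions), values)


def build_profile_matrix(matrix: BinaryMatrix, manifest: LibraryManifest) -> ProfileMatrix:
    """Average replicate rows per cell type.

    For two replicates the profile value at a feature is 1 when both show a
    peak, 0 when neither does, and 0.5 when they disagree.
    """
    cell_types = []
    for label in matrix.row_labels:
        ct = manifest.cell_type_of(label)
        if ct not in cell_types:
            cell_types.append(ct)
    rows = []
    for ct in cell_types:
        reps = [l for l in manifest.replicates_of(ct) if l in matrix.row_labels]
        if not reps:
            raise ValueError(f"cell type {ct!r} has no replicate rows in the matrix")
        idx = [matrix.row_labels.index(l) for l in reps]
        rows.append(matrix.values[idx].mean(axis=0))
    return ProfileMatrix(cell_types, list(matrix.columns), np.array(rows))


def mask_near_constant_columns(matrix: BinaryMatrix) -> BinaryMatrix:
    """Drop columns where at most one library deviates from the rest.

    Keeps exactly the columns whose minority-state count is >= 2; constant
    columns and single-deviant columns carry no reproducible grouping
    signal across replicates and are treated as noise.  Idempotent.
    """
    if matrix.shape[0] < 3:
        raise ValueError("masking requires at least 3 rows")
    ones = matrix.values.sum(axis=0)
    minority = np.minimum(ones, matrix.shape[0] - ones)
    keep = np.flatnonzero(minority >= 2)
    if keep.size == 0:
        warnings.warn("masking removed every column", stacklevel=2)
    return matrix.subset_columns(keep)


def consensus_by_cell_type(
    matrix: BinaryMatrix,
    manifest: LibraryManifest,
    cell_types: Sequence[str],
) -> tuple[BinaryMatrix, list[int]]:
    """Per-cell-type consensus over columns where replicates agree.

    A column is kept iff, for every listed cell type, all of that type's
    replicate rows carry the same value; the consensus row holds the agreed
    value.  Columns with any within-type ambiguity are dropped.
    """
    rep_idx: list[list[int]] = []
    for ct in cell_types:
        reps = [l for l in manifest.replicates_of(ct) if l in matrix.row_labels]
        if not reps:
            raise ValueError(f"unknown or absent cell type {ct!r}")
        rep_idx.append([matrix.row_labels.index(l) for l in reps])
    n_cols = matrix.shape[1]
    keep = np.ones(n_cols, dtype=bool)
    consensus = np.zeros((len(cell_types), n_cols), dtype=np.uint8)
    for t, idx in enumerate(rep_idx):
        block = matrix.values[idx]
        agree = (block == block[0]).all(axis=0)
        keep &= agree
        consensus[t] = block[0]
    kept = np.flatnonzero(keep)
    out = BinaryMatrix(list(cell_types), [matrix.columns[j] for j in kept], consensus[:, kept])
    return out, [int(j) for j in kept]


def write_regions_bed(regions: Iterable[FeatureColumn], path: str) -> None:
    """Plain BED3 export (0-based, half-open), genomically sorted."""
    with open(path, "w") as fh:
        for r in _sorted_columns(regions):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
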