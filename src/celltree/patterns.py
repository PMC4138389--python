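"""Gain/loss pattern analysis along differentiation paths.

Selects genomic regions whose mark presence is specific to one group of
libraries (e.g. all embryonic-stem-cell samples marked, everything else
unmarked, allowing a configurable number of errors per side), and counts
presence/absence patterns of unambiguous regions along an ordered path of
cell types (e.g. embryonic-stem-cell days 0, 2, 5, 9, 14).  Selected
regions export as BED for downstream enrichment tools.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .peaks import LibraryManifest
from .represent import BinaryMatrix, FeatureColumn, consensus_by_cell_type, write_regions_bed

__all__ = [
    "PatternTable",
    "MarkerRegionSet",
    "select_group_specific_regions",
    "path_pattern_counts",
    "regions_matching_pattern",
]


@dataclass
class PatternTable:
    """Counts of 0/1 presence patterns along an ordered cell-type path.

    The all-zero pattern is never included: the overlap representation
    requires a peak in at least one sample, and a region unmarked along
    the whole path carries no signal for it.
    """

    path_labels: list[str]
    counts: dict[str, int]

    def __post_init__(self) -> None:
        width = len(self.path_labels)
        for pattern in self.counts:
            if len(pattern) != width or set(pattern) - {"0", "1"}:
                raise ValueError(f"bad pattern {pattern!r} for a path of length {width}")
        if "0" * width in self.counts:
            raise ValueError("the all-zero pattern must be excluded")

    def total(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(self.path_labels) + "\tcount\n")
            for pattern in sorted(self.counts):
                fh.write("\t".join(pattern) + f"\t{self.counts[pattern]}\n")


@dataclass
class MarkerRegionSet:
    """Regions specifically marked (or unmarked) in one group of libraries."""

    direction: str  # "positive-in-group" | "negative-in-group"
    regions: list[FeatureColumn]

    def __post_init__(self) -> None:
        if self.direction not in ("positive-in-group", "negative-in-group"):
            raise ValueError(f"bad direction {self.direction!r}")
        self.regions = sorted(self.regions, key=lambda r: r.sort_key)

    def __len__(self) -> int:
        return len(self.regions)

    def to_bed(self, path: str) -> None:
        write_regions_bed(self.regions, path)


def select_group_specific_regions(
    matrix: BinaryMatrix,
    manifest: LibraryManifest,
    group_rows: Sequence[str],
    max_errors: int = 1,
) -> tuple[MarkerRegionSet, MarkerRegionSet]:
    """Columns that separate a group of libraries from all the others.

    Positive set: columns with at least ``|group| - max_errors`` ones
    inside the group and at most ``max_errors`` ones outside.  Negative
    set: the mirror condition on zeros.  ``max_errors=1`` reproduces the
    "one error allowed on each side" rule.
    """
    group = list(dict.fromkeys(group_rows))
    unknown = [g for g in group if g not in matrix.row_labels]
    if unknown:
        raise ValueError(f"group rows not in matrix: {unknown}")
    if not group or len(group) >= len(matrix.row_labels):
        raise ValueError("group must be a non-empty strict subset of matrix rows")
    n_in, n_out = len(group), len(matrix.row_labels) - len(group)
    if max_errors >= n_in or max_errors >= n_out:
        raise ValueError(
            f"max_errors={max_errors} must be smaller than both the group "
            f"size ({n_in}) and its complement ({n_out})"
        )
    in_idx = [matrix.row_labels.index(g) for g in group]
    out_idx = [i for i in range(len(matrix.row_labels)) if i not in in_idx]
    ones_in = matrix.values[in_idx].sum(axis=0)
    ones_out = matrix.values[out_idx].sum(axis=0)
    positive = (ones_in >= n_in - max_errors) & (ones_out <= max_errors)
    negative = ((n_in - ones_in) >= n_in - max_errors) & ((n_out - ones_out) <= max_errors)
    cols = np.asarray(matrix.columns, dtype=object)
    return (
        MarkerRegionSet("positive-in-group", list(cols[positive])),
        MarkerRegionSet("negative-in-group", list(cols[negative])),
    )


def path_pattern_counts(
    matrix: BinaryMatrix,
    manifest: LibraryManifest,
    path: Sequence[str],
) -> PatternTable:
    """Count consensus presence/absence patterns along an ordered path.

    Only columns where every path cell type's replicates agree are
    counted; the pattern string follows the path order left to right, and
    the all-zero pattern is excluded.
    """
    consensus, _ = consensus_by_cell_type(matrix, manifest, path)
    counts: Counter[str] = Counter()
    for j in range(consensus.shape[1]):
        pattern = "".join(str(int(v)) for v in consensus.values[:, j])
        if "1" in pattern:
            counts[pattern] += 1
    return PatternTable(list(path), dict(counts))


def regions_matching_pattern(
    matrix: BinaryMatrix,
    manifest: LibraryManifest,
    path: Sequence[str],
    pattern: str,
    bed_path: str | None = None,
) -> list[FeatureColumn]:
    """Regions whose replicate consensus along the path equals ``pattern``.

    Optionally exports them as sorted BED3 (the input format of enrichment
    tools such as GREAT).
    """
    if len(pattern) != len(path):
        raise ValueError(f"pattern length {len(pattern)} != path length {len(path)}")
    if set(pattern) - {"0", "1"}:
        raise ValueError(f"pattern must be a 0/1 string, got {pattern!r}")
    consensus, _ = consensus_by_cell_type(matrix, manifest, path)
    want = np.array([int(c) for c in pattern], dtype=np.uint8)
    hits = np.flatnonzero((consensus.values == want[:, None]).all(axis=0))
    regions = sorted((consensus.columns[j] for j in hits), key=lambda r: r.sort_key)
    if bed_path is not None:
        write_regions_bed(regions, bed_path)
    return regions
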