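"""Pairwise distances between library representations.

Hamming distance on 0/1 rows (the count of disagreeing columns) and its
profile-matrix generalisation, the Manhattan (L1) distance.  Distances are
reported as raw counts/sums; ``normalize=True`` divides by the column count
for cross-dataset comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .represent import BinaryMatrix, ProfileMatrix

__all__ = ["DistanceMatrix", "hamming_distance_matrix", "manhattan_distance_matrix"]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with row labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.diag(self.d).any():
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.d):
                fh.write(label + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str) -> "DistanceMatrix":
        with open(path) as fh:
            labels = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [line.rstrip("\n").split("\t")[1:] for line in fh if line.strip()]
        return cls(labels, np.array(rows, dtype=float))

    def to_phylip(self, path: str) -> None:
        """PHYLIP square format for interoperability."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.d):
                fh.write(f"{label:<10s}" + " ".join(f"{v:g}" for v in row) + "\n")


def hamming_distance_matrix(matrix: BinaryMatrix, normalize: bool = False) -> DistanceMatrix:
    """Number of columns at which two libraries' 0/1 rows differ."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    x = matrix.values.astype(float)
    n_cols = matrix.shape[1]
    frac = pdist(x, metric="hamming") if n_cols else np.zeros(len(matrix.row_labels) * (len(matrix.row_labels) - 1) // 2)
    d = squareform(frac * n_cols)
    if normalize and n_cols:
        d = d / n_cols
    return DistanceMatrix(list(matrix.row_labels), d)


def manhattan_distance_matrix(profile: ProfileMatrix, normalize: bool = False) -> DistanceMatrix:
    """Sum of absolute profile differences; equals Hamming on 0/1 profiles."""
    if profile.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    n = profile.shape[0]
    d = squareform(pdist(profile.values, metric="cityblock")) if profile.shape[1] else np.zeros((n, n))
    if normalize and profile.shape[1]:
        d = d / profile.shape[1]
    return DistanceMatrix(list(profile.row_labels), d)
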