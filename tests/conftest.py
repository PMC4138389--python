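import numpy as np
import pytest

from celltree import (
    BinaryMatrix,
    FeatureColumn,
    LibraryManifest,
    ManifestEntry,
    PeakInterval,
    PeakLibrary,
)


def make_library(library_id, intervals, cell_type=None, replicate=1, group="G",
                 chrom="chr1", neg_log_p=None):
    """Build a PeakLibrary from (start, end) pairs on one chromosome."""
    peaks = tuple(
        PeakInterval(chrom, s, e, neg_log_p) for s, e in intervals
    )
    return PeakLibrary(library_id, cell_type or library_id, replicate, group, peaks)


def make_manifest(spec):
    """Manifest from (library_id, cell_type, replicate, group) tuples."""
    return LibraryManifest(tuple(
        ManifestEntry(None, lid, ct, rep, grp) for lid, ct, rep, grp in spec
    ))


def make_matrix(rows, row_labels=None, kind="region"):
    """BinaryMatrix from a list of 0/1 row lists, with synthetic coordinates."""
    values = np.array(rows, dtype=np.uint8)
    n_cols = values.shape[1]
    columns = [FeatureColumn(kind, "chr1", 1000 * j, 1000 * j + 500) for j in range(n_cols)]
    labels = row_labels or [f"lib{i}" for i in range(values.shape[0])]
    return BinaryMatrix(labels, columns, values)


@pytest.fixture
def two_rep_manifest():
    """Three cell types, two replicates each (A, B) plus a singleton (C)."""
    return make_manifest([
        ("a1", "A", 1, "GrpA"),
        ("a2", "A", 2, "GrpA"),
        ("b1", "B", 1, "GrpB"),
        ("b2", "B", 2, "GrpB"),
        ("c1", "C", 1, "GrpC"),
    ])


def random_additive_instance(rng, n_taxa):
    """A random binary tree with edge lengths in [0.1, 5] and its exact
    leaf-to-leaf path-length matrix (the brute-force additive oracle)."""
    # build a random topology as a parent-array over 2n-1 nodes
    nodes = list(range(n_taxa))
    next_id = n_taxa
    parent = {}
    length = {}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent[a], parent[b] = next_id, next_id
        length[a] = rng.uniform(0.1, 5.0)
        length[b] = rng.uniform(0.1, 5.0)
        nodes = [n for n in nodes if n not in (a, b)] + [next_id]
        next_id += 1
    root = nodes[0]

    def path_to_root(v):
        path = []
        while v != root:
            path.append(v)
            v = parent[v]
        return path

    labels = [f"T{k}" for k in range(n_taxa)]
    d = np.zeros((n_taxa, n_taxa))
    for x in range(n_taxa):
        for y in range(x + 1, n_taxa):
            px, py = path_to_root(x), path_to_root(y)
            shared = set(px) & set(py)
            dist = sum(length[v] for v in px if v not in shared)
            dist += sum(length[v] for v in py if v not in shared)
            d[x, y] = d[y, x] = dist
    edges = []  # splits for RF comparison: leaf sets below each internal edge
    children = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)

    def leaves_below(v):
        if v < n_taxa:
            return {v}
        out = set()
        for c in children[v]:
            out |= leaves_below(c)
        return out

    splits = set()
    all_leaves = frozenset(range(n_taxa))
    for v in parent:
        below = frozenset(leaves_below(v))
        other = all_leaves - below
        if len(below) >= 2 and len(other) >= 2:
            splits.add(frozenset((frozenset(labels[k] for k in below),
                                  frozenset(labels[k] for k in other))))
    return labels, d, splits
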