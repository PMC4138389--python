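"""Neighbor-Joining tree inference and cell-type-tree statistics.

The inferred object is an unrooted tree over libraries (or cell types),
stored with a trifurcating root node, built on scikit-bio's ``TreeNode``.
Statistics:

* ``sr_ratio`` — fraction of total branch length carried by leaf-incident
  edges; values near 1 indicate a star-like (low-signal) tree.
* ``percent_deviation`` — mean relative disagreement between tree path
  distances and the input distance matrix, as a percentage; near 0 means
  the distances are tree-like (additive).

Transformations: collapsing replicate clades to a single cell-type leaf,
per-group purity statistics, and Robinson-Foulds topology comparison.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .distance import DistanceMatrix
from .peaks import LibraryManifest

__all__ = [
    "CellTypeTree",
    "neighbor_joining",
    "sr_ratio",
    "percent_deviation",
    "collapse_replicate_clades",
    "group_purity_stats",
    "robinson_foulds",
]


@dataclass
class CellTypeTree:
    """Unrooted tree with labelled leaves and non-negative branch lengths.

    ``clamped_branches`` counts NJ branch lengths that came out negative
    and were clamped to zero.
    """

    root: TreeNode
    clamped_branches: int = 0

    def leaf_labels(self) -> list[str]:
        return [t.name for t in self.root.tips()]

    def copy(self) -> "CellTypeTree":
        return CellTypeTree(self.root.copy(), self.clamped_branches)

    def to_newick(self, path: str | None = None) -> str:
        text = str(self.root)  # skbio writes newick with a trailing newline
        if path is not None:
            self.root.write(path)
        return text.strip()

    @classmethod
    def from_newick(cls, source: str) -> "CellTypeTree":
        """Parse newick from a string or a file path."""
        if "(" in source or ";" in source:
            root = TreeNode.read([source])
        else:
            root = TreeNode.read(source)
        return cls(root)

    def tip_distances(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (edge lengths summed)."""
        dm = self.root.tip_tip_distances()
        ids = list(dm.ids)
        return DistanceMatrix(ids, np.asarray(dm.data, dtype=float))

    def edges(self) -> list[TreeNode]:
        """Every edge, represented by its child node; excludes the root."""
        return [n for n in self.root.traverse() if not n.is_root()]


def neighbor_joining(D: DistanceMatrix, clamp_negative: bool = True) -> CellTypeTree:
    """Saitou-Nei Neighbor-Joining on a symmetric distance matrix.

    Iteratively joins the pair minimising the Q-criterion
    ``Q(i,j) = (n-2) d(i,j) - r_i - r_j`` (r = row sums), computes branch
    lengths to the new node by the standard formulas, and reduces the
    matrix; the final three nodes are resolved by the three-point formulas.

    Determinism: among tied minimal-Q pairs the lexicographically smallest
    (i, j) in current row order wins, and each join's new node is appended
    after the surviving rows.  Negative branch lengths are clamped to zero
    (count reported on the result) unless ``clamp_negative=False``.
    """
    n = len(D)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = np.array(D.d, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=l) for l in D.labels]
    clamped = 0

    def _set_length(node: TreeNode, length: float) -> None:
        nonlocal clamped
        if clamp_negative and length < 0:
            clamped += 1
            length = 0.0
        node.length = float(length)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        iu = np.triu_indices(m, k=1)
        # row-major argmin over the upper triangle -> first (lexicographically
        # smallest) pair among ties
        best = int(np.argmin(q[iu]))
        i, j = int(iu[0][best]), int(iu[1][best])
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        _set_length(nodes[i], li)
        _set_length(nodes[j], lj)
        parent.extend([nodes[i], nodes[j]])
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep],
                       new_row[keep][None, :]])
        d = np.hstack([d, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # resolve the last three nodes around a trifurcating root
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    lengths = [(d01 + d02 - d12) / 2.0, (d01 + d12 - d02) / 2.0, (d02 + d12 - d01) / 2.0]
    root = TreeNode()
    for node, length in zip(nodes, lengths):
        _set_length(node, length)
        root.append(node)
    return CellTypeTree(root, clamped)


def sr_ratio(tree: CellTypeTree) -> float:
    """Leaf-incident branch length over total branch length, in [0, 1].

    A "leaf edge" is any edge incident to a degree-1 node of the unrooted
    tree.  Star trees give exactly 1; long internal edges drive the ratio
    towards 0.  Invariant under uniform scaling of all edge lengths.
    """
    total = leaf_sum = 0.0
    for node in tree.edges():
        length = node.length or 0.0
        total += length
        if node.is_tip():
            leaf_sum += length
    if total <= 0:
        raise ValueError("SR ratio is undefined on a tree with zero total length")
    return leaf_sum / total


def percent_deviation(tree: CellTypeTree, D: DistanceMatrix) -> float:
    """Mean relative disagreement between tree and matrix distances (%).

    ``PD = 100 * mean over unordered leaf pairs with M(i,j) > 0 of
    |NJ(i,j) - M(i,j)| / M(i,j)`` where NJ(i,j) sums the edge lengths on
    the tree path.  Pairs at zero matrix distance are excluded (relative
    error is undefined there).  Zero for an additive matrix against its
    own NJ tree; 100 when every tree distance doubles the matrix distance.
    """
    tree_d = tree.tip_distances()
    if set(tree_d.labels) != set(D.labels):
        raise ValueError("tree leaves and matrix labels differ")
    devs = []
    for a, b in itertools.combinations(D.labels, 2):
        m = D.get(a, b)
        if m > 0:
            devs.append(abs(tree_d.get(a, b) - m) / m)
    if not devs:
        raise ValueError("no leaf pairs with positive matrix distance")
    return 100.0 * float(np.mean(devs))


def _pure_cell_type(node: TreeNode, type_of: dict[str, str]) -> str | None:
    """The single cell type under ``node``, or None if mixed.

    Leaves already collapsed to a cell-type label map to themselves.
    """
    names = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
    types = {type_of.get(n, n) for n in names}
    return types.pop() if len(types) == 1 else None


def collapse_replicate_clades(
    tree: CellTypeTree, manifest: LibraryManifest
) -> CellTypeTree:
    """Replace each maximal single-cell-type subtree by one cell-type leaf.

    Replicates of a cell type typically form a cherry; the cherry (or any
    larger pure clade, e.g. an embryonic-stem-cell time-course clade) is
    replaced by its attachment node, relabelled with the cell type, keeping
    the attachment edge length.  Singleton-replicate leaves are relabelled
    only.  A cell type whose replicates are not monophyletic is collapsed
    per maximal pure subtree, with a warning.
    """
    out = tree.copy()
    type_of = {label: manifest.cell_type_of(label) for label in out.leaf_labels()}
    # maximal pure subtrees: pure nodes whose parent is not pure
    collapsed_types: dict[str, int] = {}
    for node in list(out.root.postorder(include_self=False)):
        if node.parent is None:  # detached by an earlier collapse
            continue
        ct = _pure_cell_type(node, type_of)
        if ct is None:
            continue
        parent = node.parent
        parent_pure = parent is not None and not parent.is_root() and \
            _pure_cell_type(parent, type_of) is not None
        if parent_pure:
            continue
        collapsed_types[ct] = collapsed_types.get(ct, 0) + 1
        # turn the pure subtree's attachment node into a cell-type leaf,
        # keeping its position and attachment edge length
        for child in list(node.children):
            node.remove(child)
        node.name = ct
    for ct, k in collapsed_types.items():
        if k > 1:
            warnings.warn(
                f"cell type {ct!r} is not monophyletic: collapsed {k} pure subtrees",
                stacklevel=2,
            )
    return CellTypeTree(out.root, tree.clamped_branches)


def group_purity_stats(
    tree: CellTypeTree, manifest: LibraryManifest
) -> dict[str, tuple[int, int]]:
    """Sizes of the two largest group-pure subtrees for each group.

    Cutting any single edge splits the unrooted tree into two components;
    a component whose leaves all belong to one group is group-pure.  For
    each group the leaf counts of the two largest maximal pure components
    are reported (second = 0 if only one exists).  Large first components
    mean the group's libraries cluster together in the tree.
    """
    leaves = tree.leaf_labels()
    group_of = {l: manifest.group_of(l) for l in leaves}
    all_leaves = frozenset(leaves)
    candidates: set[frozenset] = set()
    for node in tree.edges():
        below = frozenset(t.name for t in node.tips()) if not node.is_tip() else frozenset({node.name})
        candidates.add(below)
        candidates.add(all_leaves - below)
    pure_sets: dict[str, list[frozenset]] = {}
    for comp in candidates:
        if not comp:
            continue
        groups = {group_of[l] for l in comp}
        if len(groups) == 1:
            pure_sets.setdefault(groups.pop(), []).append(comp)
    stats: dict[str, tuple[int, int]] = {}
    for group in sorted({g for g in group_of.values()}):
        comps = pure_sets.get(group, [])
        maximal = [c for c in comps if not any(c < o for o in comps)]
        sizes = sorted((len(c) for c in maximal), reverse=True)
        first = sizes[0] if sizes else 0
        second = sizes[1] if len(sizes) > 1 else 0
        stats[group] = (first, second)
    return stats


def _nontrivial_bipartitions(tree: CellTypeTree) -> set[frozenset]:
    """Bipartitions as frozensets of the two leaf-name sides."""
    all_leaves = frozenset(tree.leaf_labels())
    splits = set()
    for node in tree.edges():
        if node.is_tip():
            continue
        below = frozenset(t.name for t in node.tips())
        other = all_leaves - below
        if len(below) >= 2 and len(other) >= 2:
            splits.add(frozenset((below, other)))
    return splits


def robinson_foulds(t1: CellTypeTree, t2: CellTypeTree) -> int:
    """Symmetric-difference count of non-trivial bipartitions."""
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2 or len(l1) != len(t1.leaf_labels()) or len(l2) != len(t2.leaf_labels()):
        raise ValueError("trees must share an identical, duplicate-free leaf label set")
    return len(_nontrivial_bipartitions(t1) ^ _nontrivial_bipartitions(t2))
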