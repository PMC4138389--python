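"""Neighbor-Joining, newick I/O, SR/PD statistics, tree transformations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from celltree import (
    CellTypeTree,
    DistanceMatrix,
    collapse_replicate_clades,
    group_purity_stats,
    neighbor_joining,
    percent_deviation,
    robinson_foulds,
    sr_ratio,
)
from celltree.phylogeny import _nontrivial_bipartitions

from conftest import make_manifest, random_additive_instance

QUARTET = DistanceMatrix(
    ["A", "B", "C", "D"],
    np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float),
)


def leaf_edge_lengths(tree):
    return {t.name: t.length for t in tree.root.tips()}


# --- Neighbor-Joining ------------------------------------------------------

def test_nj_quartet_recovers_split_and_lengths():
    """Additive quartet: exhaustive check of the split and every edge length."""
    tree = neighbor_joining(QUARTET)
    splits = _nontrivial_bipartitions(tree)
    assert splits == {frozenset((frozenset("AB"), frozenset("CD")))}
    assert leaf_edge_lengths(tree) == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
    internal = [n.length for n in tree.edges() if not n.is_tip()]
    assert internal == [1.0]
    assert tree.clamped_branches == 0


def test_nj_three_taxa_closed_form():
    d = DistanceMatrix(["x", "y", "z"],
                       np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float))
    tree = neighbor_joining(d)
    # three-point formulas: lx=(4+6-8)/2=1, ly=(4+8-6)/2=3, lz=(6+8-4)/2=5
    assert leaf_edge_lengths(tree) == {"x": 1.0, "y": 3.0, "z": 5.0}


def test_nj_ultrametric_equidistant_taxa_gives_equal_leaf_edges():
    n = 4
    d = np.full((n, n), 2.0)
    np.fill_diagonal(d, 0.0)
    tree = neighbor_joining(DistanceMatrix([f"t{i}" for i in range(n)], d))
    lengths = set(leaf_edge_lengths(tree).values())
    assert lengths == {1.0}


def test_nj_rejects_small_or_asymmetric_input():
    with pytest.raises(ValueError, match="at least 3"):
        neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["a", "b", "c"],
                       np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_nj_consistency_on_additive_matrices(seed):
    """NJ reconstructs the generating topology exactly from any additive
    matrix, with zero percent deviation (tree metric fits perfectly)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 15))
    labels, d, true_splits = random_additive_instance(rng, n)
    D = DistanceMatrix(labels, d)
    tree = neighbor_joining(D)
    assert _nontrivial_bipartitions(tree) == true_splits
    assert percent_deviation(tree, D) == pytest.approx(0.0, abs=1e-9)


def test_nj_agrees_with_reference_implementation():
    """Cross-check topology against scikit-bio's independent NJ."""
    import io

    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(7)
    for _ in range(10):
        labels, d, _ = random_additive_instance(rng, int(rng.integers(5, 12)))
        ours = neighbor_joining(DistanceMatrix(labels, d))
        theirs = CellTypeTree(skbio_nj(SkbioDM(d, ids=labels)))
        assert robinson_foulds(ours, theirs) == 0


# --- newick I/O ------------------------------------------------------------

def test_newick_round_trip_preserves_topology_and_lengths():
    text = "(A:1.0,B:2.0,(C:3.0,D:4.0):1.0);"
    tree = CellTypeTree.from_newick(text)
    again = CellTypeTree.from_newick(tree.to_newick())
    assert robinson_foulds(tree, again) == 0
    assert leaf_edge_lengths(again) == leaf_edge_lengths(tree)
    # write . parse . write is a fixed point
    assert again.to_newick() == CellTypeTree.from_newick(again.to_newick()).to_newick()


def test_newick_quotes_labels_with_spaces(tmp_path):
    tree = neighbor_joining(DistanceMatrix(
        ["HFF MyC", "WI 38", "plain"],
        np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)))
    path = tmp_path / "t.nwk"
    tree.to_newick(str(path))
    loaded = CellTypeTree.from_newick(str(path))
    assert set(loaded.leaf_labels()) == {"HFF MyC", "WI 38", "plain"}


def test_malformed_newick_raises():
    with pytest.raises(Exception):
        CellTypeTree.from_newick("(A:1,B:2")


# --- SR ratio --------------------------------------------------------------

def test_sr_closed_forms():
    star = CellTypeTree.from_newick("(A:2,B:3,C:4,D:1);")
    assert sr_ratio(star) == pytest.approx(1.0)
    quartet = CellTypeTree.from_newick("(A:1,B:1,(C:1,D:1):1);")
    assert sr_ratio(quartet) == pytest.approx(0.8)


def test_sr_scale_invariant_and_internal_dominated_limit():
    base = CellTypeTree.from_newick("(A:1,B:1,(C:1,D:1):5);")
    scaled = CellTypeTree.from_newick("(A:10,B:10,(C:10,D:10):50);")
    assert sr_ratio(base) == pytest.approx(sr_ratio(scaled))
    heavy = CellTypeTree.from_newick("(A:0.001,B:0.001,(C:0.001,D:0.001):1000);")
    assert sr_ratio(heavy) < 0.001


def test_sr_undefined_on_zero_length_tree():
    with pytest.raises(ValueError, match="zero total length"):
        sr_ratio(CellTypeTree.from_newick("(A:0,B:0,C:0);"))


# --- percent deviation -----------------------------------------------------

def test_pd_doubling_every_edge_gives_100():
    tree = neighbor_joining(QUARTET)
    for node in tree.edges():
        node.length *= 2
    assert percent_deviation(tree, QUARTET) == pytest.approx(100.0)


def test_pd_grows_with_perturbation():
    """Perturbing matrix entries away from additivity raises PD (simulation)."""
    rng = np.random.default_rng(21)
    labels, d, _ = random_additive_instance(rng, 8)
    means = []
    for eps in (0.0, 0.5, 2.0):
        vals = []
        for rep in range(10):
            noise = rng.uniform(0, eps, size=d.shape)
            noise = np.triu(noise, 1)
            noisy = d + noise + noise.T
            D = DistanceMatrix(labels, noisy)
            vals.append(percent_deviation(neighbor_joining(D), D))
        means.append(np.mean(vals))
    assert means[0] == pytest.approx(0.0, abs=1e-9)
    assert means[0] < means[1] < means[2]


def test_pd_invariant_under_relabeling():
    tree = neighbor_joining(QUARTET)
    renamed = {"A": "w", "B": "x", "C": "y", "D": "z"}
    for tip in tree.root.tips():
        tip.name = renamed[tip.name]
    D2 = DistanceMatrix([renamed[l] for l in QUARTET.labels], QUARTET.d)
    assert percent_deviation(tree, D2) == pytest.approx(0.0, abs=1e-12)


def test_pd_label_mismatch_errors():
    tree = neighbor_joining(QUARTET)
    bad = DistanceMatrix(["A", "B", "C", "E"], QUARTET.d)
    with pytest.raises(ValueError, match="labels differ"):
        percent_deviation(tree, bad)


# --- collapsing replicate clades -------------------------------------------

REP_MANIFEST = make_manifest([
    ("a1", "A", 1, "G1"), ("a2", "A", 2, "G1"),
    ("b1", "B", 1, "G1"), ("b2", "B", 2, "G1"),
    ("c", "C", 1, "G2"),
])


def test_collapse_cherries_to_cell_type_leaves():
    tree = CellTypeTree.from_newick("((a1:5,a2:5):1,(b1:4,b2:6):1,c:3);")
    collapsed = collapse_replicate_clades(tree, REP_MANIFEST)
    assert sorted(collapsed.leaf_labels()) == ["A", "B", "C"]
    assert leaf_edge_lengths(collapsed) == {"A": 1.0, "B": 1.0, "C": 3.0}


def test_collapse_relabels_singletons_without_topology_change():
    manifest = make_manifest([("x1", "X", 1, "G"), ("y1", "Y", 1, "G"),
                              ("z1", "Z", 1, "G")])
    tree = CellTypeTree.from_newick("(x1:1,y1:2,z1:3);")
    collapsed = collapse_replicate_clades(tree, manifest)
    assert sorted(collapsed.leaf_labels()) == ["X", "Y", "Z"]
    assert leaf_edge_lengths(collapsed) == {"X": 1.0, "Y": 2.0, "Z": 3.0}


def test_collapse_whole_multi_leaf_clade():
    """A five-leaf single-type clade (e.g. a stem-cell time course) collapses
    to one leaf at its attachment edge."""
    manifest = make_manifest(
        [(f"es{i}", "ES", i, "ES") for i in range(1, 6)]
        + [("u1", "U", 1, "G"), ("v1", "V", 1, "G")])
    tree = CellTypeTree.from_newick(
        "(((es1:1,es2:1):1,(es3:1,(es4:1,es5:1):1):1):7,u1:2,v1:2);")
    collapsed = collapse_replicate_clades(tree, manifest)
    assert sorted(collapsed.leaf_labels()) == ["ES", "U", "V"]
    assert leaf_edge_lengths(collapsed)["ES"] == 7.0


def test_collapse_non_monophyletic_warns_and_preserves_others():
    manifest = make_manifest([
        ("a1", "A", 1, "G"), ("a2", "A", 2, "G"),
        ("b1", "B", 1, "G"), ("b2", "B", 2, "G"),
    ])
    # A's replicates split by b1: not monophyletic
    tree = CellTypeTree.from_newick("((a1:1,b1:1):1,a2:1,b2:1);")
    with pytest.warns(UserWarning, match="not monophyletic"):
        collapsed = collapse_replicate_clades(tree, manifest)
    assert sorted(collapsed.leaf_labels()) == ["A", "A", "B", "B"]


def test_collapse_preserves_distances_among_untouched_leaves():
    tree = CellTypeTree.from_newick("((a1:5,a2:5):1,(b1:4,b2:6):2,c:3);")
    before = tree.tip_distances()
    collapsed = collapse_replicate_clades(tree, REP_MANIFEST)
    after = collapsed.tip_distances()
    # c was a singleton: its path to the collapsed attachment points shrinks
    # by the cherry depth but inter-attachment structure is intact
    assert after.get("A", "B") == pytest.approx(3.0)  # 1 + 2
    assert after.get("A", "C") == pytest.approx(4.0)  # 1 + 3
    assert len(collapsed.leaf_labels()) <= len(before.labels)


# --- group purity ----------------------------------------------------------

def test_group_purity_counts_two_largest_pure_subtrees():
    manifest = make_manifest([
        ("h1", "H", 1, "hESC"), ("h2", "H", 2, "hESC"), ("h3", "H", 3, "hESC"),
        ("h4", "H", 4, "hESC"), ("h5", "H", 5, "hESC"),
        ("f1", "F", 1, "Fib"), ("f2", "F", 2, "Fib"), ("f3", "F", 3, "Fib"),
        ("e1", "E", 1, "Epi"),
    ])
    tree = CellTypeTree.from_newick(
        "(((h1:1,h2:1):1,(h3:1,(h4:1,h5:1):1):1):1,((f1:1,f2:1):1,e1:1):1,f3:1);")
    stats = group_purity_stats(tree, manifest)
    assert stats["hESC"] == (5, 0)
    assert stats["Fib"] == (2, 1)
    assert stats["Epi"] == (1, 0)


def test_group_purity_complement_side_counts():
    """A pure component can be the complement of a clade (unrooted cut)."""
    manifest = make_manifest([
        ("g1", "T1", 1, "G"), ("g2", "T2", 1, "G"), ("g3", "T3", 1, "G"),
        ("x1", "X", 1, "Other"),
    ])
    tree = CellTypeTree.from_newick("(g1:1,g2:1,(g3:1,x1:1):1);")
    stats = group_purity_stats(tree, manifest)
    # cutting the edge above x1 leaves {g1,g2,g3} pure on the far side
    assert stats["G"] == (3, 0)
    assert stats["Other"] == (1, 0)


# --- Robinson-Foulds -------------------------------------------------------

def test_rf_identical_and_alternative_quartets():
    t1 = CellTypeTree.from_newick("((A:1,B:1):1,C:1,D:1);")
    t2 = CellTypeTree.from_newick("((A:1,C:1):1,B:1,D:1);")
    assert robinson_foulds(t1, t1) == 0
    assert robinson_foulds(t1, t2) == 2


def test_rf_matches_brute_force_split_enumeration():
    caterpillar = CellTypeTree.from_newick(
        "(A:1,B:1,(C:1,(D:1,(E:1,F:1):1):1):1);")
    balanced = CellTypeTree.from_newick(
        "((A:1,B:1):1,(C:1,D:1):1,(E:1,F:1):1);")
    s1 = _nontrivial_bipartitions(caterpillar)
    s2 = _nontrivial_bipartitions(balanced)
    assert robinson_foulds(caterpillar, balanced) == len(s1 ^ s2)
    # independent oracle: dendropy's RF on the same newick strings
    import dendropy

    taxa = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=caterpillar.to_newick(), schema="newick",
                           taxon_namespace=taxa)
    d2 = dendropy.Tree.get(data=balanced.to_newick(), schema="newick",
                           taxon_namespace=taxa)
    expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
    assert robinson_foulds(caterpillar, balanced) == expected


def test_rf_leaf_set_mismatch_errors():
    t1 = CellTypeTree.from_newick("(A:1,B:1,C:1);")
    t2 = CellTypeTree.from_newick("(A:1,B:1,Z:1);")
    with pytest.raises(ValueError, match="leaf label set"):
        robinson_foulds(t1, t2)
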