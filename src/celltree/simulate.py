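"""Synthetic peak libraries with known ground truth.

Emulates the generative picture behind cell-type trees: a binary mark
state per genomic region evolves along a known bifurcating differentiation
tree, with independent per-edge gain/loss flips; replicates of each leaf
cell type add independent flip noise; emitted peaks get jittered
boundaries and per-peak significance scores.  Because the generating tree
and all node states are retained, the whole pipeline (representation ->
distance -> NJ -> collapse) can be scored for topology recovery.

Defaults encode the study conditions used throughout the test-suite: 12
cell types x 2 replicates, 5000 regions, per-edge flip probabilities drawn
uniformly from [0.02, 0.1], replicate flip probability 0.01.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .distance import hamming_distance_matrix
from .peaks import (
    LibraryManifest,
    ManifestEntry,
    PeakInterval,
    PeakLibrary,
    write_manifest,
    write_peak_file,
)
from .phylogeny import (
    CellTypeTree,
    collapse_replicate_clades,
    neighbor_joining,
    percent_deviation,
    robinson_foulds,
    sr_ratio,
)
from .represent import BinaryMatrix, FeatureColumn, build_overlap_matrix

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "RecoveryReport",
    "simulate_gain_loss",
    "emit_peak_libraries",
    "write_dataset",
    "recovery_harness",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the gain/loss simulation.

    ``edge_flip_prob`` may be a single probability or a ``(low, high)``
    pair, in which case each edge draws its own flip probability uniformly
    from that range.  ``boundary_jitter_bp`` must stay below half the gap
    (so jitter cannot merge adjacent truth regions) and below half the
    region length (so a jittered peak still covers its own region).
    """

    n_cell_types: int = 12
    replicates_per_type: int = 2
    n_regions: int = 5000
    root_presence_prob: float = 0.5
    edge_flip_prob: float | tuple[float, float] = (0.02, 0.1)
    replicate_flip_prob: float = 0.01
    region_length_bp: int = 600
    gap_bp: int = 400
    boundary_jitter_bp: int = 100
    significant_fraction: float = 0.8
    chrom: str = "chrSim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 3:
            raise ValueError("need at least 3 cell types")
        if self.replicates_per_type < 1:
            raise ValueError("need at least 1 replicate per type")
        if self.n_regions < 1:
            raise ValueError("need at least 1 region")
        probs = [self.root_presence_prob, self.replicate_flip_prob, self.significant_fraction]
        lo, hi = self._edge_prob_range()
        if not (0 <= lo <= hi < 0.5):
            raise ValueError("edge_flip_prob must lie in [0, 0.5)")
        if not all(0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.replicate_flip_prob >= 0.5:
            raise ValueError("replicate_flip_prob must be < 0.5")
        if self.boundary_jitter_bp >= self.gap_bp / 2:
            raise ValueError("boundary_jitter_bp must be < gap_bp / 2")
        if self.boundary_jitter_bp >= self.region_length_bp / 2:
            raise ValueError("boundary_jitter_bp must be < region_length_bp / 2")

    def _edge_prob_range(self) -> tuple[float, float]:
        if isinstance(self.edge_flip_prob, (int, float)):
            return float(self.edge_flip_prob), float(self.edge_flip_prob)
        lo, hi = self.edge_flip_prob
        return float(lo), float(hi)

    def cell_type_names(self) -> list[str]:
        width = len(str(self.n_cell_types))
        return [f"CT{i + 1:0{width}d}" for i in range(self.n_cell_types)]


@dataclass
class TruthRecord:
    """Ground truth of one simulation: tree, per-node states, coordinates."""

    true_tree: CellTypeTree
    node_states: dict[str, np.ndarray]  # node name -> 0/1 vector over regions
    region_coordinates: list[FeatureColumn]

    def leaf_matrix(self) -> BinaryMatrix:
        """Leaf cell-type states as a binary matrix (all regions)."""
        labels = sorted(self.true_tree.leaf_labels())
        values = np.array([self.node_states[l] for l in labels], dtype=np.uint8)
        return BinaryMatrix(labels, list(self.region_coordinates), values)


def _random_bifurcating_tree(names: list[str], rng: np.random.Generator) -> TreeNode:
    """Uniformly random rooted labelled bifurcating topology.

    Stepwise addition: insert each leaf on a uniformly chosen existing
    edge (including the root edge), which makes every labelled topology
    equally likely for a fixed insertion order.
    """
    root = TreeNode(name=names[0])
    for name in names[1:]:
        edges = list(root.traverse())  # every node = edge above it (root = root edge)
        target = edges[int(rng.integers(len(edges)))]
        new = TreeNode()
        leaf = TreeNode(name=name)
        if target.parent is None:
            new.extend([target, leaf])
            root = new
        else:
            parent = target.parent
            idx = parent.children.index(target)
            parent.remove(target)
            new.extend([target, leaf])
            parent.append(new)
    return root


def simulate_gain_loss(config: SimulationConfig) -> TruthRecord:
    """Evolve per-region binary states along a random differentiation tree.

    The root state of each region is Bernoulli(root_presence_prob); along
    each edge every region flips independently with that edge's flip
    probability.  Gains and losses share one rate by default.  Fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    names = config.cell_type_names()
    root = _random_bifurcating_tree(names, rng)
    # stable internal node names for the state record
    counter = 0
    for node in root.preorder():
        if node.name is None:
            node.name = f"anc{counter}"
            counter += 1
    lo, hi = config._edge_prob_range()
    node_states: dict[str, np.ndarray] = {}
    root_state = (rng.random(config.n_regions) < config.root_presence_prob).astype(np.uint8)
    node_states[root.name] = root_state
    for node in root.preorder():
        if node.is_root():
            continue
        p = lo if lo == hi else float(rng.uniform(lo, hi))
        node.length = p  # simulated edge "length" is its flip probability
        flips = rng.random(config.n_regions) < p
        node_states[node.name] = node_states[node.parent.name] ^ flips.astype(np.uint8)
    period = config.region_length_bp + config.gap_bp
    coords = [
        FeatureColumn("region", config.chrom, r * period, r * period + config.region_length_bp)
        for r in range(config.n_regions)
    ]
    return TruthRecord(CellTypeTree(root), node_states, coords)


def _draw_neg_log_p(rng: np.random.Generator, n: int, significant_fraction: float) -> np.ndarray:
    """Mixture score model: a configurable fraction clears threshold 10.

    Significant peaks score 10 + Exponential(mean 5); the rest score
    Uniform[0, 10).
    """
    significant = rng.random(n) < significant_fraction
    scores = rng.uniform(0.0, 10.0, size=n)
    scores[significant] = 10.0 + rng.exponential(5.0, size=int(significant.sum()))
    return scores


def emit_peak_libraries(
    truth: TruthRecord, config: SimulationConfig
) -> tuple[list[PeakLibrary], LibraryManifest]:
    """Materialise replicate peak libraries from the truth leaf states.

    Each replicate copies its cell type's state vector, flips entries
    independently with ``replicate_flip_prob``, and turns every 1 into a
    peak on the synthetic chromosome with endpoints jittered by up to
    ``boundary_jitter_bp``; each peak gets a -log10 p-value from the
    mixture score model.  The emission stream is seeded independently of
    the tree/state stream so the truth is stable across noise settings.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    libraries: list[PeakLibrary] = []
    entries: list[ManifestEntry] = []
    j = config.boundary_jitter_bp
    for ct in sorted(truth.true_tree.leaf_labels()):
        state = truth.node_states[ct]
        for rep in range(1, config.replicates_per_type + 1):
            flips = rng.random(config.n_regions) < config.replicate_flip_prob
            observed = state ^ flips.astype(np.uint8)
            present = np.flatnonzero(observed)
            starts = np.array([truth.region_coordinates[r].start for r in present])
            ends = np.array([truth.region_coordinates[r].end for r in present])
            if j > 0 and present.size:
                starts = starts + rng.integers(-j, j + 1, size=present.size)
                ends = ends + rng.integers(-j, j + 1, size=present.size)
                starts = np.maximum(starts, 0)
            scores = _draw_neg_log_p(rng, present.size, config.significant_fraction)
            peaks = tuple(
                PeakInterval(config.chrom, int(s), int(e), float(p))
                for s, e, p in zip(starts, ends, scores)
            )
            lib_id = f"{ct}_r{rep}"
            libraries.append(PeakLibrary(lib_id, ct, rep, ct, peaks))
            entries.append(ManifestEntry(None, lib_id, ct, rep, ct))
    return libraries, LibraryManifest(tuple(entries))


def write_dataset(truth: TruthRecord, config: SimulationConfig, out_dir: str | os.PathLike) -> LibraryManifest:
    """Write narrowPeak files, manifest, truth newick and truth matrix TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    libraries, manifest = emit_peak_libraries(truth, config)
    entries = []
    for lib in libraries:
        name = f"{lib.library_id}.narrowPeak"
        write_peak_file(lib.peaks, out / name, dialect="narrowPeak")
        # bare filenames: the manifest sits next to the peak files, and
        # relative paths resolve against the manifest's directory on load
        entries.append(ManifestEntry(name, lib.library_id, lib.cell_type,
                                     lib.replicate, lib.group))
    manifest = LibraryManifest(tuple(entries))
    write_manifest(manifest, out / "manifest.tsv")
    truth.true_tree.to_newick(str(out / "truth.nwk"))
    truth.leaf_matrix().to_tsv(str(out / "truth_matrix.tsv"))
    return manifest


@dataclass
class RecoveryReport:
    """End-to-end pipeline score against the simulation's ground truth.

    ``rf_distance`` is None when the collapsed tree has duplicated
    cell-type labels (non-monophyletic replicates), in which case the
    topology was by definition not recovered.
    """

    rf_distance: int | None
    sr: float
    pd_percent: float
    clamped_branches: int
    n_regions_observed: int
    inferred_tree: CellTypeTree
    collapsed_tree: CellTypeTree


def recovery_harness(config: SimulationConfig) -> RecoveryReport:
    """Simulate, run the full inference pipeline, score against truth.

    emit -> overlap representation -> Hamming -> NJ -> collapse replicate
    clades -> Robinson-Foulds against the generating topology.
    Deterministic given ``config.seed``.
    """
    truth = simulate_gain_loss(config)
    libraries, manifest = emit_peak_libraries(truth, config)
    _, matrix = build_overlap_matrix(libraries)
    D = hamming_distance_matrix(matrix)
    tree = neighbor_joining(D)
    collapsed = collapse_replicate_clades(tree, manifest)
    labels = collapsed.leaf_labels()
    if len(labels) == len(set(labels)):
        rf = robinson_foulds(collapsed, truth.true_tree)
    else:
        rf = None
    return RecoveryReport(
        rf_distance=rf,
        sr=sr_ratio(tree),
        pd_percent=percent_deviation(tree, D),
        clamped_branches=tree.clamped_branches,
        n_regions_observed=matrix.shape[1],
        inferred_tree=tree,
        collapsed_tree=collapsed,
    )
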