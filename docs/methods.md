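# Methods

## Model

Cell differentiation is modelled as a tree over cell types in which a
histone mark can be independently gained or lost in each genomic region
along each edge. Presence/absence of a mark in a region is therefore a
binary character inherited with noise, and the differentiation history is
recoverable by distance-based phylogenetics. No substitution model exists
for histone marks, so inference is deliberately model-free:
Neighbor-Joining on Hamming distances, which assumes only that observed
distances are approximately additive along the tree. The independence
assumption across regions is a simplification — real marks covary through
domain-scale chromatin state — but it is what makes the per-region coding
and the Hamming distance meaningful.

## Representations

**Windowing.** Bins of `bin_size` bp (default 200, roughly one nucleosome
footprint of 147 bp plus linker). A bin is 1 for a library iff any peak
overlaps the bin interval; "contains at least one peak" is implemented as
any-overlap, since containment would drop small peaks placed across a bin
boundary. Bins that are zero in every library are not materialised: they
cannot change any pairwise Hamming distance and would make matrices
genome-sized. Consequence: each library's row is independent of which
other libraries are loaded, but the materialised column set is not.

**Overlap.** Interesting regions are the connected components of the
interval graph over the pooled peaks of all libraries, computed by a
single left-to-right sweep per chromosome over the sorted pooled peaks
(linear after sorting). Intervals are half-open `[start, end)`;
touching intervals (`[0,10)` and `[10,20)`) do not overlap and belong to
different components. The result is unique for a given input; columns are
sorted genomically (chromosome lexicographic, then start) for
deterministic serialization. Unlike windowing, a library's row depends on
the full library set, because the regions do.

**Profile.** Per cell type, the mean of its replicates' 0/1 values —
with two replicates: 0, 0.5 or 1. Distances on profiles are Manhattan
sums, which reduce exactly to Hamming on 0/1-valued profiles.

## Filters

* **Significance**: keep peaks with −log10 p ≥ threshold, inclusive;
  requires a dialect that carries the p-value column (narrowPeak and
  broadPeak use column 8, per the ENCODE format; a generic `bed+p`
  dialect takes a user-supplied 1-based column index).
* **Masking**: drop columns whose minority-state count is ≤ 1 (constant
  columns and single-deviant columns). Applied across all rows of the
  supplied matrix; callers subset rows first if they want per-mark
  masking. Idempotent by construction.
* **Consensus**: for path analyses, keep only columns where every listed
  cell type's replicates agree; singleton-replicate types can never be
  ambiguous.

## Neighbor-Joining

Standard Saitou–Nei: join the pair minimising
`Q(i,j) = (n−2)·d(i,j) − r_i − r_j`, branch lengths
`l_i = d(i,j)/2 + (r_i − r_j)/(2(n−2))`, matrix reduction
`d(u,k) = (d(i,k) + d(j,k) − d(i,j))/2`, final three nodes resolved by
the three-point formulas around a trifurcating root (the standard
encoding of an unrooted tree). Determinism: ties in Q resolve to the
lexicographically smallest (i, j) in current row order (numpy's
first-minimum over the row-major upper triangle), and each join's new row
is appended after the surviving rows. Negative branch lengths — a known
NJ artefact on noisy data — are clamped to zero at assignment and
counted on the result (`clamped_branches`); SR and PD are computed on the
clamped lengths.

## Tree statistics

**SR** sums leaf-incident edge lengths over total edge length. "Leaf
edge" means any edge incident to a degree-1 node of the unrooted tree.
Undefined (error) for an all-zero-length tree; invariant under uniform
scaling.

**PD** is `100 × mean over unordered leaf pairs with M(i,j) > 0 of
|T(i,j) − M(i,j)| / M(i,j)`. Pairs at zero matrix distance are excluded
— identical libraries would divide by zero, and they carry no fit
information. The mean (rather than a sum) keeps PD comparable across
taxon counts; this averaging convention is stated in the `stats` CLI
output. Exactly 0 for an additive matrix against its own NJ tree; exactly
100 when every tree distance doubles the matrix distance.

**Collapsing.** A maximal subtree whose leaves all belong to one cell
type is replaced by its attachment node, relabelled with the cell type
and keeping the attachment edge length; singleton leaves are relabelled
only. Cherries are the common case; larger pure clades (a stem-cell
time course, say) collapse the same way. Non-monophyletic replicate sets
collapse per maximal pure subtree with a warning and duplicate labels.
Purity is evaluated on the trifurcating-root encoding; a pure set
straddling the root would be missed, which cannot happen for the
replicate-pair cherries this operation targets.

**Group purity.** Cutting one edge splits the unrooted tree into two
components; both sides of every edge are candidate group-pure subtrees.
For each group the two largest maximal pure components are reported
(second = 0 if only one exists). O(n²) set operations — trees here have
at most ~100 leaves.

**Robinson–Foulds** counts the symmetric difference of non-trivial
bipartitions, computed from leaf-set splits so that rooted and
trifurcating-root encodings compare correctly.

## Synthetic data

The simulator emulates: a uniformly random rooted labelled bifurcating
topology (stepwise addition — each leaf inserted on a uniformly chosen
existing edge including the root edge); per-region root states
Bernoulli(`root_presence_prob` = 0.5); independent per-edge, per-region
state flips; per-replicate flip noise; peak boundary jitter; and per-peak
−log10 p-values from a documented mixture (with probability
`significant_fraction` = 0.8 the score is 10 + Exponential(mean 5),
otherwise Uniform[0, 10)) so significance filtering at threshold 10 is
exercisable. Gains and losses share one flip rate by default; real
development is loss-biased, and an asymmetric extension would only
require separate gain/loss probabilities per edge.

Defaults are the study conditions used throughout the tests: 12 cell
types × 2 replicates, 5000 regions, per-edge flip probabilities drawn
uniformly from [0.02, 0.1] (edge "lengths" are the flip probabilities),
replicate flip probability 0.01, regions of 600 bp separated by 400 bp
gaps, jitter ≤ 100 bp. The jitter bound is validated against half the
gap (adjacent truth regions can never merge) and half the region length
(a jittered peak always covers part of its own region), which makes the
region → peaks → overlap-representation round trip exact at zero noise.

What the simulator does **not** emulate: read-level noise and peak-caller
bias (beyond boundary jitter and flips), correlated gain/loss across
neighbouring regions, chromosome structure (one synthetic chromosome,
evenly spaced regions), copy-number or mappability artefacts, and
biological heterogeneity between individuals. Passing recovery tests
therefore demonstrate the pipeline's correctness under its own model, not
performance on real ChIP-Seq noise.

Determinism: one `numpy` Generator seeded from `seed` drives tree and
states; emission uses a child stream spawned from the same seed, so the
truth record is identical across noise settings and output files are
byte-identical across runs.

## Recovery harness and pilot calibration

`recovery_harness` runs emit → overlap representation → Hamming → NJ →
collapse → Robinson–Foulds against the generating topology. When
collapsing yields duplicate cell-type labels (non-monophyletic
replicates) RF is reported as None and counted as a failed recovery. A
20-seed pilot at the default conditions during development gave RF = 0 in
19 of 20 seeds (the single failure had a very short internal edge
relative to the noise floor, the expected failure mode); the end-to-end
test asserts at least 18 of 20.

## Numerical and scale choices

* Hamming/Manhattan via `scipy.spatial.distance.pdist`; distances are raw
  counts/sums by default (`normalize=True` divides by column count).
* Test problem sizes — up to 20 libraries × 200 peaks for the
  interval-graph oracle, 5–30 taxa for NJ consistency, 5000 regions for
  the recovery study — keep the whole suite under a minute while leaving
  each property's failure modes reachable.
* The brute-force oracles (pairwise-overlap interval graph with
  union-find components; exhaustive bipartition enumeration; exact path
  metrics on random trees) are implemented independently of the
  production code paths they check.

## Known limitations

* No maximum-parsimony or maximum-likelihood inference, no bootstrap
  support, no rooting, no ancestral-state reconstruction: tree inference
  here is NJ only.
* Overlap columns depend on the library set, so matrices built from
  different library subsets are not column-compatible.
* Masking and consensus assume replicate labels are trustworthy; swapped
  replicates silently weaken both filters.
* RF comparison requires duplicate-free leaf label sets; non-monophyletic
  collapses must be resolved (or leaves pruned) before comparing.
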