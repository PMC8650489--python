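# Methods

This note documents the models, estimators and numerical choices behind
`nmigraph`, in the order the pipeline applies them.

## Signal selection

Analysis operates on ROI-averaged time series restricted to task-block
volumes. Motion censoring removes any volume whose differential head
movement exceeds 0.5 mm per TR; a volume at exactly 0.5 mm is kept
(the censoring rule is strictly greater-than). Censored volumes are
dropped, never interpolated. Task selection and censoring are both pure
mask intersections, so their order is irrelevant; no per-block minimum
volume count is enforced. ROI extraction from 4-D volumes is a plain
arithmetic mean over the voxels of each atlas label; labels with no
voxels are excluded with a warning rather than an error so that small
fixture grids remain usable.

## NMI connectivity

Pairwise dependence between two ROI series x, y is

    NMI(x, y) = I(x; y) / sqrt(H(x) · H(y)),

with I and H plug-in estimates from equal-width histograms. Each series
is binned over its own observed range; the joint histogram uses the same
per-axis edges. Properties: NMI ∈ [0, 1], symmetric, 0 for an exactly
factorizing joint, 1 for identical series, and invariant to the
logarithm base (the base cancels in the ratio).

Choices that the estimator's definition leaves open:

* **Bin count.** Default `ceil(sqrt(n_samples))` bins per axis (19 bins
  at 180 retained volumes). This is the standard plug-in heuristic; it
  is configurable (`n_bins`) and recorded in the report provenance.
* **Degenerate series.** A constant series has zero entropy; its NMI is
  defined as 0 and flagged, never NaN, since a flat signal carries no
  information.
* **Clamping.** Plug-in MI can dip a rounding error below zero; MI is
  clamped to ≥ 0 and NMI into [0, 1].
* **Exact symmetry.** Entropy terms sum probabilities in sorted order,
  and the whole-matrix builder (a single indicator-matrix product that
  yields every pairwise joint histogram at once) symmetrizes exactly, so
  `NMI(x, y) == NMI(y, x)` holds bit-for-bit.

The plug-in estimator is biased upward for finite samples (independent
Gaussian pairs of length 180 at 19 bins sit near NMI ≈ 0.17 rather than
0). The pipeline's thresholding is rank-based, so this common-mode bias
does not affect which edges survive.

## Graph construction

Each subject's NMI matrix defines a fully dense weighted undirected
graph (zero diagonal; ROIs as nodes). Stages, with their conventions:

1. **Density thresholding (default 50%).** Exactly
   `floor(target · N(N−1)/2)` strongest edges are retained. Removal
   order is ascending weight, ties broken by ascending (i, j) node-index
   pair, making the result bit-reproducible. Graphs at or below the
   target are returned unchanged; the operation is idempotent.
2. **Nodal elimination (default 5%).** Nodes with degree strictly below
   `0.05 · (N − 1)` are removed, with N the node count at entry to this
   step (post-thresholding). The rule is applied once — no fixed-point
   iteration — followed by a single sweep dropping nodes the first pass
   left fully disconnected.
3. **Group reduction.** Every subject graph is restricted to the
   intersection of the group's node sets (order follows the first
   subject).
4. **Group averaging.** Edgewise arithmetic mean of the thresholded
   subject matrices (zeros included), then a second thresholding pass to
   the target density. Averaging many sparse supports produces a dense
   matrix, hence the re-threshold.

The per-group surviving node count is itself a reported statistic.

## Network metrics

* **Degree / strength**: edge count and weight sum per node, both
  divided by the node count N so networks in different node spaces stay
  comparable. (At 50% density mean normalized degree is ≈ 0.5 by
  construction.)
* **Clustering**: cube-root (geometric-mean) triangle intensity,
  `C_i = 2 t_i / (k_i (k_i − 1))` with
  `t_i = ½ Σ (w_ij w_ih w_jh)^{1/3}`; `C_i = 0` for degree < 2. NMI
  weights already lie in [0, 1], so no re-normalization by the maximum
  weight is applied (note: networkx's implementation does rescale by the
  max; the two agree after undoing that factor, which the test suite
  exploits as a cross-check).
* **Global efficiency**: mean inverse shortest-path length over ordered
  node pairs, with edge length = 1/weight; disconnected pairs contribute
  0. Paths via Dijkstra (scipy); an O(N³) Floyd–Warshall loop lives in
  the tests as the independent oracle. The per-node decomposition
  (mean inverse distance from each node) is retained because the group
  comparison permutes nodal values (below).

## Modular decomposition

Newman modularity of a partition on a weighted graph:

    Q = (1/2m) Σ_ij [ w_ij − s_i s_j / (2m) ] δ(c_i, c_j).

One optimizer run combines four complementary local-search phases, all
exact-bookkeeping on Q:

1. a random-order sweep moving each node to its best module while Q
   improves (the run's main source of seed-to-seed diversity);
2. greedy pairwise agglomeration from the current partition down to a
   single module, keeping the best point of the trajectory;
3. spectral bisection of each module (leading eigenvector of the
   generalized modularity matrix) refined by Kernighan-Lin sign flips;
4. pairwise repartitioning: for every module pair, the union is re-split
   by Kernighan-Lin starting from current membership (this finds
   coordinated multi-node transfers and pair merges);
5. Kernighan-Lin single-node move sweeps over the whole graph (best
   move applied even when Q-decreasing, node locked, best prefix kept).

Phases 2–5 loop until none improves Q. Each run additionally descends
from both the random-order start and a plain singleton start and keeps
the better result. Ties among equal-gain moves are resolved uniformly at
random from the run's seed. On random graphs of ≤ 8 nodes the optimizer
matched exhaustive search over all set partitions in 300/300 sampled
instances; like all modularity heuristics it carries no global-optimality
guarantee.

**Consensus.** The final decomposition is a consensus over `n_mod_runs`
(default 100) seeded runs. "Averaging" nominal module labels is only
meaningful after alignment, so each run's labels are matched to the
first run's by greedy maximum-overlap assignment; each node then takes
its modal aligned label (ties → smallest label); the module containing
node 1 is relabeled 1 and labels made contiguous by first appearance;
one final refinement pass restores local optimality, and Q of the
consensus is reported.

**Partition distance.** Two partitions are compared by the variation of
information from the module-overlap contingency table, normalized by
log N: pd ∈ [0, 1], zero iff the partitions agree up to relabeling,
symmetric, and a metric. Group partitions live on different node sets,
so the cross-group pd is computed on the node intersection.

## Hub taxonomy

With k, s the (raw) degree and strength vectors of one network:

* **Hub**: `k_i ≥ mean(k) + sd(k)` and `s_i ≥ mean(s) + sd(s)` (sample
  SD, ddof = 1). If a metric's SD is zero (all nodes tie) it singles out
  nobody and no node can be a hub through it.
* **High-influence**: non-hub nodes in the top 30% for both degree and
  strength. Ranks are descending with minimum-rank ties; if ties push
  more than `ceil(0.3 N)` nodes past the cutoff, the selection is
  truncated to `ceil(0.3 N)` by node order for determinism. Ranking is
  over all nodes; hubs are excluded afterwards.
* **Connector vs provincial**: participation coefficient
  `pc_i = 1 − Σ_m (k_im / k_i)²` over binary per-module edge counts;
  hubs with `pc_i ≥ 0.9 · (1 − 1/M)` (90% of the theoretical even-split
  maximum for M modules) are connectors, the rest provincial. A
  single-module partition makes the maximum 0; all hubs are then
  provincial and a warning is raised.

The four classes (connector, provincial, high-influence, other) are
exhaustive and disjoint. Hub comparisons across networks are descriptive
(shared/gained/lost node sets); no significance test is attached.

## Permutation inference

Group differences use a two-tailed permutation test on the Welch t
statistic: pooled values are randomly reassigned to groups of the
original sizes, default 20,000 Monte-Carlo randomizations, p-value
`(#{|t*| ≥ |t_obs|} + 1)/(n_perm + 1)` so p is never 0. When the
assignment space `C(n_a + n_b, n_a)` is at most 10,000 the test switches
to exhaustive enumeration and is exact. Bonferroni thresholds are plain
`alpha / m` (default m = 20, giving 0.0025 at alpha = 0.05).

**Permutation unit.** The group networks are single objects, so the
observations entering the metric comparisons are the per-node metric
values of the two group networks, and permutation reassigns
node-to-network labels. This is the only reading consistent with
reporting per-network dispersions over nodes; it tests differences in
the nodal-metric distributions of the two averaged networks, not
subject-level variability. For efficiency, the nodal decomposition of
global efficiency is used so the same machinery applies.

**Partition-distance test.** The null shuffles one partition's labels
across nodes (preserving module sizes) and recomputes pd; the p-value is
the fraction of null distances ≤ the observed one (+1 smoothing). Small
p means the two decompositions are *more similar than chance* — the
hypothesis a claim of difference must reject. The direction is a
documented choice surfaced in the report provenance.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes, not
fMRI physics:

* **Design**: 15 blocks of 30 s task + 30 s rest at TR 2.5 s → 360
  volumes, 180 of them task.
* **Signal**: ROI r in module m follows
  `x_r(t) = w · z_m(t) + b · g(t) + ε` during task volumes and pure
  noise ε ~ N(0, noise_sd²) at rest, with z_m independent standard
  Gaussian module latents and g a global latent shared by all modules
  (the "between-module leakage"). Only task volumes carry community
  structure, mirroring the analysis using task volumes only.
* **Defaults** (the full-scale preset): 212 ROIs named by compartment
  (142 ctx / 36 sub / 34 cbl), 3 planted modules in contiguous thirds,
  within-coupling 0.6, between-coupling 0.1, noise SD 1.0, groups of 26
  ("control") and 20 ("patient"); the patient group couples 0.15 more
  strongly within modules and has its last 20 ROIs inactive — planting
  the qualitative direction of the group effects the inference stage
  should detect (higher clustering, fewer recruited nodes).
* **Motion**: a uniform [0, 0.2] mm baseline plus 1.0 mm spikes placed
  Bernoulli(0.05) per volume, exercising the censoring path with
  deterministic spike placement.

Every subject is a pure function of `(cohort seed, subject index)`, so
cohorts are bit-reproducible. What the generator deliberately does not
model: hemodynamic response convolution, autocorrelated scanner noise,
spatial smoothness, realistic anatomy. Passing tests therefore show the
estimators and the pipeline logic are correct on data with the assumed
statistical structure; they do not show robustness to fMRI noise
spectra.

## Problem sizes used in the checks

The planted-recovery experiment uses 60-ROI, 3-module single subjects
(within 0.9, between 0.0) over 10 seeds — small enough to run in
seconds while leaving the recovery non-trivial. Calibration uses 500
null replicates of 20-vs-20 samples at 1,000 permutations. The
structural end-to-end check runs the full-scale preset (212 ROIs, 360
volumes, 46 subjects) with all defaults.

## Known limitations

* The histogram NMI estimator's bias floor means absolute NMI values are
  not comparable across different bin counts or sample sizes; only
  within-pipeline ranks are used.
* The node-level permutation unit (above) cannot speak to between-subject
  variability; subject-level inference would need per-subject networks
  in the comparison, which the group-averaged design does not produce.
* Consensus over label-aligned modal assignment can, in principle,
  produce a partition that is not a local optimum; the final refinement
  pass repairs this but may then deviate from the strict per-node mode.
* `eliminate_sparse_nodes` is single-pass by design; a disconnection
  cascade longer than one step would survive (not observed at the
  default densities, where thresholded graphs are far above the 5%
  line).
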