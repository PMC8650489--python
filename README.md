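# nmigraph

Graph-theoretical analysis of task-fMRI functional brain networks built
on normalized mutual information (NMI) connectivity.

The package is for researchers who want to characterize how a task
reorganizes whole-brain functional networks between groups (for example
patients with a task-specific dystonia versus healthy controls): it
turns per-subject ROI time series into weighted undirected graphs,
reduces them to comparable group networks, and quantifies their
segregation, integration, community structure and hub architecture,
with non-parametric inference throughout.

## What it computes

For ROI time series x, y (task volumes only, motion-censored at
0.5 mm/TR), connectivity is the normalized mutual information

    NMI(x, y) = I(x; y) / √(H(x) H(y)) ∈ [0, 1],

estimated from equal-width histograms. Each subject's NMI matrix becomes
a weighted graph, thresholded to 50% density by removing the weakest
edges; nodes with fewer than 5% of possible connections are eliminated.
Group networks are the edgewise means over subjects (on the common node
set), re-thresholded to 50%. On each network the package computes:

* normalized nodal degree k_i/N and strength s_i/N,
* the weighted clustering coefficient (geometric mean of triangle
  weights, cube-root form),
* global efficiency (mean inverse shortest-path length, edge length =
  1/weight),
* the optimal modular decomposition by Newman-modularity maximization
  with Kernighan-Lin refinement, consensus over 100 randomized runs,
* partition distance between group decompositions (variation of
  information / log N) with a permutation test,
* a hub taxonomy (connector / provincial hubs, high-influence nodes)
  from degree, strength and the participation coefficient
  pc_i = 1 − Σ_m (k_im/k_i)²,
* two-tailed Monte-Carlo permutation t-tests (20,000 randomizations)
  with Bonferroni correction for the group metric comparisons.

A synthetic-cohort generator with planted modular structure, group
effects and motion spikes makes the whole pipeline runnable and testable
without any imaging data. See `docs/methods.md` for the estimators,
conventions and design choices in detail.

## Worked example

Write a config for a small synthetic two-group cohort and run the full
pipeline:

```yaml
# config.yaml
cohort:
  preset: small          # 60 ROIs, 3 planted modules
  seed: 11
  n_rois: 60
  n_per_group: {A: 4, B: 4}
  within: 0.8            # within-module coupling
  between: 0.1
n_mod_runs: 50
n_perm: 2000
seed: 11
```

```text
$ nmigraph run-all --config config.yaml --out results
[A] 59 nodes, density 0.500, 3 modules (Q = 0.330)
[B] 60 nodes, density 0.500, 3 modules (Q = 0.352)
report: results/report.json

$ nmigraph report --report results/report.json
group A: N=59 (of 60), degree 0.491±0.105, clustering 0.096±0.012, Eglob 0.119, modules 3
group B: N=60 (of 60), degree 0.492±0.097, clustering 0.098±0.013, Eglob 0.119, modules 3
A_vs_B: pd = 0.000 (p = 0.0004998)
  degree_norm: t = -0.023, p = 0.9865
  strength_norm: t = -0.208, p = 0.8406
  clustering: t = -0.860, p = 0.3933
  efficiency: t = 0.109, p = 0.912
```

Reading the output: both group networks sit exactly at the 50% density
target; 59 of 60 ROIs survived elimination in group A. The consensus
decomposition recovers the three planted modules in both groups
(Q ≈ 0.33–0.35), and the partition distance between the group
decompositions is 0 — identical up to relabeling — with p ≈ 5·10⁻⁴
against the shuffled-labels null (far more similar than chance). The
two groups were generated identically here, so none of the nodal-metric
permutation tests approaches the Bonferroni threshold (0.0025).

The same analysis runs from on-disk data by replacing `cohort:` with
`manifest: path/to/manifest.tsv` (one time-series TSV and one motion TSV
per subject; see `nmigraph simulate` for the layout). Individual stages
are exposed as `nmigraph connect`, `build` and `analyze`, and the whole
library is importable (`import nmigraph`).

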