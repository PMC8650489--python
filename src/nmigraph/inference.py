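"""Permutation inference: two-tailed Monte-Carlo t-tests and the
partition-distance significance test.

Group differences are assessed with a non-parametric permutation t-test:
the Welch t statistic is computed on the observed labels, then the pooled
values are randomly reassigned to groups of the original sizes (default
20,000 Monte-Carlo randomizations) to build the null.  Two-tailed
p-values use the |t| ordering with +1 smoothing so p is never 0.  When
the label-assignment space is small (<= 10,000 distinct assignments) the
test switches to exhaustive enumeration and is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .community import ModularPartition, partition_distance

__all__ = [
    "PermutationResult",
    "permutation_ttest",
    "bonferroni_threshold",
    "partition_distance_test",
]

_EXHAUSTIVE_LIMIT = 10_000


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    p_value: float
    n_perm: int
    seed: int | None
    exhaustive: bool = False


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    diff = a.mean() - b.mean()
    se2 = a.var(ddof=1) / na + b.var(ddof=1) / nb
    if se2 == 0.0:
        return 0.0 if diff == 0.0 else np.sign(diff) * np.inf
    return float(diff / np.sqrt(se2))


def _welch_t_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t for permuted splits (rows = permutations)."""
    na, nb = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    se2 = a.var(axis=1, ddof=1) / na + b.var(axis=1, ddof=1) / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, diff / np.sqrt(se2),
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    return t


def permutation_ttest(a, b, n_perm: int = 20_000, seed: int | None = None) -> PermutationResult:
    """Two-tailed permutation test on the Welch t statistic.

    Monte-Carlo p = (#{|t*| >= |t_obs|} + 1) / (n_perm + 1).  If the
    number of distinct group assignments C(n_a + n_b, n_a) is at most
    10,000 the full assignment space is enumerated instead and the exact
    p = #{|t*| >= |t_obs|} / n_assignments is returned (the identity
    assignment guarantees p > 0).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples contain non-finite values")
    pooled = np.concatenate([a, b])
    na = a.size
    t_obs = _welch_t(a, b)

    n_assign = comb(pooled.size, na)
    if n_assign <= _EXHAUSTIVE_LIMIT:
        count = 0
        for combo in combinations(range(pooled.size), na):
            sel = np.zeros(pooled.size, dtype=bool)
            sel[list(combo)] = True
            t_star = _welch_t(pooled[sel], pooled[~sel])
            if abs(t_star) >= abs(t_obs) - 1e-12:
                count += 1
        return PermutationResult(observed=t_obs, p_value=count / n_assign,
                                 n_perm=n_assign, seed=seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    mat = np.tile(pooled, (n_perm, 1))
    rng.permuted(mat, axis=1, out=mat)
    t_star = _welch_t_rows(mat[:, :na], mat[:, na:])
    count = int(np.count_nonzero(np.abs(t_star) >= abs(t_obs) - 1e-12))
    p = (count + 1) / (n_perm + 1)
    return PermutationResult(observed=t_obs, p_value=p, n_perm=n_perm, seed=seed)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance level alpha / m."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def partition_distance_test(p: ModularPartition, q: ModularPartition,
                            n_perm: int = 20_000, seed: int | None = None) -> PermutationResult:
    """Is the observed partition distance smaller than chance?

    The null shuffles q's affiliation labels across nodes (preserving
    module sizes) and recomputes pd against p; the p-value is the
    +1-smoothed fraction of null distances <= the observed one.  A small
    p-value means the two decompositions are more similar than random
    relabelings — the premise a claim of *difference* must reject.
    """
    if p.node_names != q.node_names:
        raise ValueError("partitions are over different node sets")
    observed = partition_distance(p, q)
    rng = np.random.default_rng(seed)
    labels = q.affiliation
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if partition_distance(p.affiliation, perm) <= observed + 1e-12:
            count += 1
    p_val = (count + 1) / (n_perm + 1)
    return PermutationResult(observed=observed, p_value=p_val,
                             n_perm=n_perm, seed=seed)
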