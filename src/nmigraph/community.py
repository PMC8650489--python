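"""Optimal modular decomposition and partition comparison.

Communities are found by maximizing Newman's modularity

    Q = (1/2m) * sum_ij [ w_ij - s_i s_j / (2m) ] * delta(c_i, c_j)

over node partitions, where s is nodal strength and 2m the total weight.
The optimizer starts from singleton modules, greedily agglomerates
modules while any merge improves Q, and then refines by Kernighan-Lin
single-node reassignment sweeps: in each sweep the best single-node move
(possibly Q-decreasing) is applied and the node locked, and at the end
the sweep is rolled back to its best prefix.  Tie-breaking among
equal-gain moves is uniform from the run's seed.

Because the heuristic is randomized, the final decomposition is a
consensus over many runs (default 100): each run's labels are aligned to
the first run by maximum-overlap matching, each node takes its modal
aligned label, the module containing node 1 is relabeled 1, and one last
refinement sweep restores local optimality.

Partitions are compared by the variation of information normalized by
log N, a [0, 1] metric that is 0 exactly for identical partitions (up to
relabeling) and 1 for maximally uninformative pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netbuild import BrainGraph

__all__ = [
    "ModularPartition",
    "newman_modularity",
    "optimize_modularity",
    "consensus_partition",
    "partition_distance",
]

_TOL = 1e-12


@dataclass
class ModularPartition:
    """Node -> module affiliation (labels 1..M, node 1's module labeled 1)."""

    affiliation: np.ndarray
    q: float
    n_runs: int
    node_names: list[str]

    def __post_init__(self) -> None:
        self.affiliation = np.asarray(self.affiliation, dtype=np.int64)
        labs = np.unique(self.affiliation)
        if labs.min() < 1 or not np.array_equal(labs, np.arange(1, labs.size + 1)):
            raise ValueError("module labels must be contiguous 1..M")
        if len(self.node_names) != self.affiliation.size:
            raise ValueError("node_names length mismatch")

    @property
    def n_modules(self) -> int:
        return int(self.affiliation.max())

    def restrict(self, names: list[str]) -> "ModularPartition":
        """Partition restricted to a node subset, labels recompacted."""
        index = {n: i for i, n in enumerate(self.node_names)}
        idx = np.array([index[n] for n in names])
        return ModularPartition(
            affiliation=_canonical_labels(self.affiliation[idx]),
            q=float("nan"), n_runs=self.n_runs, node_names=list(names))


def _as_affiliation(partition) -> np.ndarray:
    if isinstance(partition, ModularPartition):
        return partition.affiliation
    return np.asarray(partition, dtype=np.int64)


def _compact(labels: np.ndarray) -> np.ndarray:
    """Relabel to contiguous 0..M-1 (arbitrary order)."""
    return np.unique(labels, return_inverse=True)[1]


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Contiguous 1..M in order of first appearance; node 1's module -> 1."""
    labels = np.asarray(labels)
    out = np.empty(labels.size, dtype=np.int64)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def _modularity(W: np.ndarray, s: np.ndarray, m2: float, labels: np.ndarray) -> float:
    lab = _compact(labels)
    m_mod = lab.max() + 1
    ind = np.zeros((labels.size, m_mod))
    ind[np.arange(labels.size), lab] = 1.0
    e = ind.T @ W @ ind
    strengths = ind.T @ s
    return float(np.trace(e) / m2 - np.sum((strengths / m2) ** 2))


def newman_modularity(g: BrainGraph, partition) -> float:
    """Q of a partition on a weighted graph; zero-edge graphs are an error."""
    labels = _as_affiliation(partition)
    if labels.size != g.n_nodes:
        raise ValueError("partition must cover all nodes")
    m2 = g.adjacency.sum()
    if m2 <= 0:
        raise ValueError("modularity undefined on a graph with no edges")
    return _modularity(g.adjacency, g.strengths(), m2, labels)


def _rng_choice_max(rng: np.random.Generator, values: np.ndarray) -> tuple:
    """Index of the maximum, ties resolved uniformly at random."""
    best = values.max()
    cands = np.argwhere(values >= best - _TOL)
    return tuple(cands[rng.integers(len(cands))])


def _merge_phase(labels: np.ndarray, W: np.ndarray, s: np.ndarray, m2: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Greedy agglomeration: repeatedly merge the module pair with the
    largest Q gain (even when negative) down to a single module, then keep
    the partition at the best point of the trajectory.  Returns the new
    labels and the Q gain relative to the input partition."""
    lab = _compact(labels)
    n_mod = lab.max() + 1
    ind = np.zeros((lab.size, n_mod))
    ind[np.arange(lab.size), lab] = 1.0
    e = ind.T @ W @ ind           # cross-module weights; diagonal double-counts
    strengths = e.sum(axis=1)      # module strengths
    active = np.ones(n_mod, dtype=bool)
    parent = np.arange(n_mod)
    cum = 0.0
    best_cum = 0.0
    best_step = -1
    merges: list[tuple[int, int]] = []
    while active.sum() >= 2:
        gains = 2.0 * e / m2 - 2.0 * np.outer(strengths, strengths) / m2**2
        gains[~active, :] = -np.inf
        gains[:, ~active] = -np.inf
        np.fill_diagonal(gains, -np.inf)
        a, b = _rng_choice_max(rng, gains)
        cum += gains[a, b]
        e[a, :] += e[b, :]
        e[:, a] += e[:, b]
        strengths[a] += strengths[b]
        active[b] = False
        e[b, :] = 0.0
        e[:, b] = 0.0
        strengths[b] = 0.0
        merges.append((a, b))
        if cum > best_cum + _TOL:
            best_cum = cum
            best_step = len(merges) - 1
    for step in range(best_step + 1):
        a, b = merges[step]
        parent[parent == b] = parent[a]
    return parent[lab], best_cum


def _kl_pass(labels: np.ndarray, W: np.ndarray, s: np.ndarray, m2: float,
             rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """One Kernighan-Lin sweep: apply the globally best single-node move
    (even if Q-decreasing), lock the node, repeat until all locked, then
    roll back to the best prefix.  One spare empty module allows splits."""
    n = labels.size
    lab = _compact(labels)
    start = lab.copy()
    n_mod = lab.max() + 1
    ind = np.zeros((n, n_mod + 1))
    ind[np.arange(n), lab] = 1.0
    wm = W @ ind                              # node-to-module weights
    strengths = ind.T @ s                     # module strengths (last = empty)
    cur = lab.copy()
    locked = np.zeros(n, dtype=bool)
    cum = 0.0
    best_cum = 0.0
    best_step = -1
    moves: list[tuple[int, int]] = []
    two_s2 = 2.0 * s**2 / m2**2
    for _ in range(n):
        g_mat = 2.0 * wm / m2 - 2.0 * np.outer(s, strengths) / m2**2
        own = g_mat[np.arange(n), cur]
        delta = g_mat - own[:, None] - two_s2[:, None]
        delta[np.arange(n), cur] = -np.inf
        delta[locked, :] = -np.inf
        # a singleton moving to the empty module is a no-op relabel; forbid
        sizes = np.bincount(cur, minlength=wm.shape[1])
        singles = sizes[cur] == 1
        delta[singles, -1] = -np.inf
        if not np.isfinite(delta).any():
            break
        i, b = _rng_choice_max(rng, delta)
        a = cur[i]
        gain = delta[i, b]
        wm[:, a] -= W[:, i]
        wm[:, b] += W[:, i]
        strengths[a] -= s[i]
        strengths[b] += s[i]
        cur[i] = b
        locked[i] = True
        if b == wm.shape[1] - 1:  # spare module now occupied; add a new one
            wm = np.column_stack([wm, np.zeros(n)])
            strengths = np.append(strengths, 0.0)
        cum += gain
        moves.append((i, b))
        if cum > best_cum + _TOL:
            best_cum = cum
            best_step = len(moves) - 1
    final = start.copy()
    for step in range(best_step + 1):
        i, b = moves[step]
        final[i] = b
    return final, best_cum


def _kl_refine(labels: np.ndarray, W: np.ndarray, s: np.ndarray, m2: float,
               rng: np.random.Generator) -> tuple[np.ndarray, float]:
    total = 0.0
    while True:
        labels, gain = _kl_pass(labels, W, s, m2, rng)
        if gain <= _TOL:
            return labels, total
        total += gain


def _subdivision_matrix(W: np.ndarray, s: np.ndarray, m2: float,
                        idx: np.ndarray) -> np.ndarray:
    """Generalized modularity matrix of a node subset: re-splitting the
    subset by a sign vector u changes Q proportionally to u' Bg u, with
    u = all-ones (no split) giving exactly zero."""
    b = W[np.ix_(idx, idx)] - np.outer(s[idx], s[idx]) / m2
    return b - np.diag(b.sum(axis=1))


def _bisection_finetune(bg: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Kernighan-Lin sign-flip refinement of a bisection vector.

    Each pass flips the best node (even when worsening), locks it, repeats
    until all nodes are locked, and rolls back to the best prefix; passes
    repeat until one brings no improvement."""
    n = u.size
    best_u = u.copy()
    best_f = float(u @ bg @ u)
    while True:
        u = best_u.copy()
        cur_f = pass_best = float(u @ bg @ u)
        pass_u = u.copy()
        locked = np.zeros(n, dtype=bool)
        for _ in range(n):
            deltas = -4.0 * u * (bg @ u) + 4.0 * np.diag(bg)
            deltas[locked] = -np.inf
            i = int(np.argmax(deltas))
            if not np.isfinite(deltas[i]):
                break
            cur_f += deltas[i]
            u[i] = -u[i]
            locked[i] = True
            if cur_f > pass_best + _TOL:
                pass_best = cur_f
                pass_u = u.copy()
        if pass_best <= best_f + _TOL:
            return best_u
        best_f = pass_best
        best_u = pass_u


def _apply_bisection(lab: np.ndarray, idx: np.ndarray, side: np.ndarray,
                     W: np.ndarray, s: np.ndarray, m2: float, q_before: float,
                     next_label: int) -> tuple[np.ndarray, float]:
    """Accept a re-split of the subset ``idx`` into sides iff it raises Q."""
    trial = lab.copy()
    trial[idx] = next_label
    if side.any() and not side.all():
        trial[idx[~side]] = next_label + 1
    dq = _modularity(W, s, m2, trial) - q_before
    if dq > _TOL:
        return trial, dq
    return lab, 0.0


def _split_phase(labels: np.ndarray, W: np.ndarray, s: np.ndarray, m2: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Try to bisect each module along the leading eigenvector of its
    generalized modularity matrix, fine-tuned by Kernighan-Lin sign flips;
    accept a split only when it raises Q.  Escapes over-merged optima that
    single-node moves cannot leave."""
    lab = _compact(labels)
    q_before = _modularity(W, s, m2, lab)
    gain_total = 0.0
    next_label = lab.max() + 1
    for c in np.unique(lab):
        idx = np.flatnonzero(lab == c)
        if idx.size < 2:
            continue
        bg = _subdivision_matrix(W, s, m2, idx)
        v = np.linalg.eigh(bg)[1][:, -1]
        u = _bisection_finetune(bg, np.where(v >= 0, 1.0, -1.0))
        lab, dq = _apply_bisection(lab, idx, u > 0, W, s, m2, q_before,
                                   next_label)
        if dq > 0.0:
            q_before += dq
            gain_total += dq
            next_label += 2
    return lab, gain_total


def _repartition_phase(labels: np.ndarray, W: np.ndarray, s: np.ndarray,
                       m2: float, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """For every pair of modules, re-bisect their union starting from the
    current membership with Kernighan-Lin sign flips; accept when Q rises.
    Finds coordinated multi-node transfers (or pair merges) that neither
    single-node moves nor within-module splits can reach."""
    lab = _compact(labels)
    q_before = _modularity(W, s, m2, lab)
    gain_total = 0.0
    next_label = lab.max() + 1
    mods = list(np.unique(lab))
    for ai in range(len(mods)):
        for bi in range(ai + 1, len(mods)):
            idx = np.flatnonzero((lab == mods[ai]) | (lab == mods[bi]))
            if idx.size < 2:
                continue
            bg = _subdivision_matrix(W, s, m2, idx)
            u0 = np.where(lab[idx] == mods[ai], 1.0, -1.0)
            u = _bisection_finetune(bg, u0)
            lab, dq = _apply_bisection(lab, idx, u > 0, W, s, m2, q_before,
                                       next_label)
            if dq > 0.0:
                q_before += dq
                gain_total += dq
                next_label += 2
    return lab, gain_total


def _louvain_sweep(labels: np.ndarray, W: np.ndarray, s: np.ndarray, m2: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Visit nodes in random order, moving each to its best module (or a new
    one) when the move raises Q; repeat until a full sweep changes nothing.
    The random visiting order is the main source of run-to-run diversity."""
    n = labels.size
    lab = _compact(labels)
    n_mod = lab.max() + 1
    ind = np.zeros((n, n_mod + 1))
    ind[np.arange(n), lab] = 1.0
    wm = W @ ind
    strengths = ind.T @ s
    two_s2 = 2.0 * s**2 / m2**2
    total = 0.0
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            a = lab[i]
            gains = 2.0 * wm[i] / m2 - 2.0 * s[i] * strengths / m2**2
            delta = gains - gains[a] - two_s2[i]
            delta[a] = -np.inf
            if np.count_nonzero(lab == a) == 1:
                delta[-1] = -np.inf  # singleton to empty module is a no-op
            b = int(np.argmax(delta))
            if delta[b] <= _TOL:
                continue
            wm[:, a] -= W[:, i]
            wm[:, b] += W[:, i]
            strengths[a] -= s[i]
            strengths[b] += s[i]
            lab[i] = b
            total += delta[b]
            improved = True
            if b == wm.shape[1] - 1:
                wm = np.column_stack([wm, np.zeros(n)])
                strengths = np.append(strengths, 0.0)
    return lab, total


def optimize_modularity(g: BrainGraph, seed: int = 0) -> ModularPartition:
    """One randomized modularity-maximization run.

    Starts from singleton modules and alternates greedy agglomeration with
    Kernighan-Lin refinement until neither phase improves Q.  Q never
    decreases across iterations; tie-breaking and sweep choices derive
    from ``seed``.
    """
    W = g.adjacency
    m2 = W.sum()
    if m2 <= 0:
        raise ValueError("cannot optimize modularity of a graph with no edges")
    s = g.strengths()
    rng = np.random.default_rng(seed)
    def _descend(labels: np.ndarray) -> np.ndarray:
        while True:
            labels, gain_m = _merge_phase(labels, W, s, m2, rng)
            labels, gain_s = _split_phase(labels, W, s, m2, rng)
            labels, gain_r = _repartition_phase(labels, W, s, m2, rng)
            labels, gain_k = _kl_refine(labels, W, s, m2, rng)
            if gain_m + gain_s + gain_r + gain_k <= _TOL:
                break
        return labels

    # two starts per run: a random-order local sweep (the run-to-run
    # diversity the consensus averages over) and plain singleton
    # agglomeration; keep whichever ends higher
    seeded, _ = _louvain_sweep(np.arange(g.n_nodes), W, s, m2, rng)
    cand_a = _descend(seeded)
    cand_b = _descend(np.arange(g.n_nodes))
    q_a = _modularity(W, s, m2, cand_a)
    q_b = _modularity(W, s, m2, cand_b)
    labels = cand_a if q_a >= q_b - _TOL else cand_b
    return ModularPartition(
        affiliation=_canonical_labels(labels),
        q=_modularity(W, s, m2, labels),
        n_runs=1,
        node_names=list(g.node_names),
    )


def _align_to_reference(ref: np.ndarray, lab: np.ndarray) -> np.ndarray:
    """Relabel ``lab`` to maximize overlap with ``ref`` (greedy matching)."""
    ref_ids = np.unique(ref)
    lab_ids = np.unique(lab)
    cont = np.zeros((lab_ids.size, ref_ids.size), dtype=np.int64)
    for li, l in enumerate(lab_ids):
        for ri, r in enumerate(ref_ids):
            cont[li, ri] = np.count_nonzero((lab == l) & (ref == r))
    mapping: dict[int, int] = {}
    used_ref: set[int] = set()
    order = np.dstack(np.unravel_index(
        np.argsort(cont, axis=None)[::-1], cont.shape))[0]
    for li, ri in order:
        l, r = int(lab_ids[li]), int(ref_ids[ri])
        if l in mapping or r in used_ref:
            continue
        mapping[l] = r
        used_ref.add(r)
    next_label = int(ref_ids.max()) + 1
    out = np.empty_like(lab)
    for li, l in enumerate(lab_ids):
        if l not in mapping:
            mapping[l] = next_label
            next_label += 1
    for i, l in enumerate(lab):
        out[i] = mapping[int(l)]
    return out


def consensus_partition(g: BrainGraph, n_runs: int = 100, seed: int = 0) -> ModularPartition:
    """Consensus decomposition over repeated randomized optimization runs.

    Runs :func:`optimize_modularity` ``n_runs`` times with seeds derived
    from ``seed``, aligns every run's labels to the first run by greedy
    maximum-overlap matching, assigns each node its modal aligned label
    (ties -> smallest label), relabels so the module containing node 1 is
    module 1, and applies one final refinement sweep so the consensus is a
    local optimum of Q.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    runs = [optimize_modularity(g, int(sd)) for sd in run_seeds]
    ref = runs[0].affiliation
    aligned = np.empty((n_runs, g.n_nodes), dtype=np.int64)
    aligned[0] = ref
    for r in range(1, n_runs):
        aligned[r] = _align_to_reference(ref, runs[r].affiliation)
    # per-node modal label across aligned runs
    consensus = np.empty(g.n_nodes, dtype=np.int64)
    for i in range(g.n_nodes):
        vals, counts = np.unique(aligned[:, i], return_counts=True)
        consensus[i] = vals[np.argmax(counts)]  # ties -> smallest label
    W = g.adjacency
    m2 = W.sum()
    s = g.strengths()
    consensus, _ = _kl_refine(_compact(consensus), W, s, m2, rng)
    return ModularPartition(
        affiliation=_canonical_labels(consensus),
        q=_modularity(W, s, m2, consensus),
        n_runs=n_runs,
        node_names=list(g.node_names),
    )


def partition_distance(p, q) -> float:
    """Normalized variation of information between two partitions.

    VI(P, Q) = H(P) + H(Q) - 2 I(P; Q) from the module-overlap
    contingency table, divided by log N so the result lies in [0, 1].
    Invariant under module relabeling; 0 iff the partitions agree.
    """
    a = _as_affiliation(p)
    b = _as_affiliation(q)
    if a.size != b.size:
        raise ValueError("partitions must cover the same node set")
    n = a.size
    if n < 2:
        return 0.0
    if (isinstance(p, ModularPartition) and isinstance(q, ModularPartition)
            and p.node_names != q.node_names):
        raise ValueError("partitions are over different node sets")
    ai = _compact(a)
    bi = _compact(b)
    cont = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(cont, (ai, bi), 1.0)
    pab = cont / n
    pa = pab.sum(axis=1)
    pb = pab.sum(axis=0)

    def h(x):
        # sorted so identical probability multisets give bitwise-equal sums
        x = np.sort(x[x > 0])
        return float(-np.sum(x * np.log(x)))

    h_a = h(pa)
    h_b = h(pb)
    h_ab = h(pab.ravel())
    # VI = H(P) + H(Q) - 2 I(P;Q) with I = H(P) + H(Q) - H(P,Q)
    vi = max(2.0 * h_ab - h_a - h_b, 0.0)
    return min(vi / np.log(n), 1.0)
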