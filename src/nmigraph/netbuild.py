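"""Graph assembly: density thresholding, nodal elimination, group averaging.

A subject's NMI matrix defines a fully dense weighted undirected graph.
Because very dense networks drift toward random-graph behaviour, each
graph is thresholded to a target edge density (default 50%) by removing
the weakest edges; nodes left with fewer than 5% of possible connections
are then eliminated as likely noise, and fully disconnected nodes are
dropped.  Group networks are built by restricting every subject to the
group's common node set, averaging the thresholded matrices edgewise, and
thresholding the average back to the target density.  The number of nodes
surviving per group is itself a reported statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BrainGraph",
    "from_connectivity",
    "graph_density",
    "threshold_to_density",
    "eliminate_sparse_nodes",
    "reduce_to_common_nodes",
    "group_average_network",
]


@dataclass
class BrainGraph:
    """Weighted undirected graph over named ROIs.

    ``adjacency`` is symmetric with zero diagonal; weight 0 means "no
    edge".  ``n_original`` remembers the parcellation size before any
    node elimination, for reporting.
    """

    adjacency: np.ndarray
    node_names: list[str]
    n_original: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got {a.shape}")
        if len(self.node_names) != a.shape[0]:
            raise ValueError("node_names length does not match adjacency")
        if not np.allclose(a, a.T, atol=0.0):
            raise ValueError("adjacency must be exactly symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(a < 0):
            raise ValueError("edge weights must be non-negative")
        self.adjacency = a
        if self.n_original <= 0:
            self.n_original = a.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    def degrees(self) -> np.ndarray:
        return (self.adjacency > 0).sum(axis=1)

    def strengths(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def subgraph(self, keep: np.ndarray) -> "BrainGraph":
        """Restriction to the given node index array, order preserved."""
        keep = np.asarray(keep)
        return BrainGraph(
            adjacency=self.adjacency[np.ix_(keep, keep)],
            node_names=[self.node_names[i] for i in keep],
            n_original=self.n_original,
        )


def from_connectivity(cm) -> BrainGraph:
    """BrainGraph with NMI values as edge weights (ROIs as nodes)."""
    return BrainGraph(adjacency=np.array(cm.weights, dtype=float),
                      node_names=list(cm.roi_names))


def graph_density(g: BrainGraph) -> float:
    """Present edges (nonzero weight) over possible edges N(N-1)/2."""
    n = g.n_nodes
    if n < 2:
        raise ValueError("density needs >= 2 nodes")
    return g.n_edges / (n * (n - 1) / 2)


def _edge_list(a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(a.shape[0], 1)
    w = a[iu, ju]
    present = w > 0
    return iu[present], ju[present], w[present]


def threshold_to_density(g: BrainGraph, target: float = 0.5) -> BrainGraph:
    """Remove the weakest edges until at most ``target`` density remains.

    Exactly ``floor(target * N(N-1)/2)`` strongest edges are retained
    (fewer if the graph already has fewer).  Removal order is ascending
    weight with ties broken by ascending (i, j) node-index pair, so the
    result is bit-reproducible.  A graph already at or below the target is
    returned unchanged.
    """
    if not (0.0 < target <= 1.0):
        raise ValueError(f"target density must lie in (0, 1], got {target}")
    n = g.n_nodes
    possible = n * (n - 1) // 2
    k = int(np.floor(target * possible))
    i, j, w = _edge_list(g.adjacency)
    if w.size <= k:
        return BrainGraph(adjacency=g.adjacency.copy(),
                          node_names=list(g.node_names), n_original=g.n_original)
    # removal order: ascending weight, then ascending (i, j)
    order = np.lexsort((j, i, w))
    drop = order[: w.size - k]
    a = g.adjacency.copy()
    a[i[drop], j[drop]] = 0.0
    a[j[drop], i[drop]] = 0.0
    return BrainGraph(adjacency=a, node_names=list(g.node_names),
                      n_original=g.n_original)


def eliminate_sparse_nodes(g: BrainGraph, min_frac: float = 0.05) -> BrainGraph:
    """Drop sparsely connected nodes, then any node left without edges.

    A node is sparse when its degree is strictly below
    ``min_frac * (N - 1)`` with N the node count at entry.  The rule is
    applied once (no fixed-point iteration), followed by a single sweep
    removing nodes that the first pass left fully disconnected.
    """
    if min_frac < 0:
        raise ValueError("min_frac must be >= 0")
    n = g.n_nodes
    deg = g.degrees()
    keep = np.flatnonzero(deg >= min_frac * (n - 1))
    reduced = g.subgraph(keep)
    deg2 = reduced.degrees()
    connected = np.flatnonzero(deg2 > 0)
    if connected.size < reduced.n_nodes:
        reduced = reduced.subgraph(connected)
    return reduced


def reduce_to_common_nodes(graphs: list[BrainGraph]) -> list[BrainGraph]:
    """Restrict every graph to the nodes present in all of them.

    Node order follows the first graph.  An empty intersection is a hard
    error.
    """
    if not graphs:
        raise ValueError("need at least one graph")
    common = set(graphs[0].node_names)
    for g in graphs[1:]:
        common &= set(g.node_names)
    if not common:
        raise ValueError("node-name intersection across subjects is empty")
    order = [name for name in graphs[0].node_names if name in common]
    out = []
    for g in graphs:
        index = {name: i for i, name in enumerate(g.node_names)}
        out.append(g.subgraph(np.array([index[name] for name in order])))
    return out


def group_average_network(graphs: list[BrainGraph], target: float = 0.5) -> BrainGraph:
    """Edgewise mean of subject graphs, re-thresholded to the target density.

    All graphs must share the same node set and order (apply
    :func:`reduce_to_common_nodes` first).  Averaging many sparse supports
    typically yields a dense matrix, hence the second thresholding pass.
    """
    if not graphs:
        raise ValueError("need at least one graph")
    names = graphs[0].node_names
    for g in graphs[1:]:
        if g.node_names != names:
            raise ValueError("graphs must share an identical node set/order; "
                             "run reduce_to_common_nodes first")
    mean = np.mean([g.adjacency for g in graphs], axis=0)
    avg = BrainGraph(adjacency=mean, node_names=list(names),
                     n_original=graphs[0].n_original)
    return threshold_to_density(avg, target)
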