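"""Weighted network metrics: degree, strength, clustering, efficiency.

Degree and strength are normalized by the node count so networks living
in different node spaces stay comparable.  Segregation is measured by the
weighted clustering coefficient (geometric mean of the three edge weights
in each triangle through a node, cube-root form); integration by global
efficiency, the average inverse shortest-path length with edge length
defined as the inverse edge weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .netbuild import BrainGraph

__all__ = [
    "NodalMetrics",
    "nodal_degree",
    "nodal_strength",
    "clustering_coefficients",
    "efficiency_contributions",
    "global_efficiency",
    "compute_nodal_metrics",
]


@dataclass
class NodalMetrics:
    """Per-node metric table for one network."""

    node_names: list[str]
    degree_norm: np.ndarray
    strength_norm: np.ndarray
    clustering: np.ndarray
    efficiency: np.ndarray  # per-node mean inverse distance to all others

    def summary(self) -> dict:
        """Mean +/- sample SD per metric, plus global efficiency."""
        def ms(x):
            return {"mean": float(np.mean(x)),
                    "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0}
        return {
            "degree_norm": ms(self.degree_norm),
            "strength_norm": ms(self.strength_norm),
            "clustering": ms(self.clustering),
            "global_efficiency": float(np.mean(self.efficiency)),
            "n_nodes": len(self.node_names),
        }


def nodal_degree(g: BrainGraph) -> np.ndarray:
    """Number of edges per node, divided by the node count N."""
    if g.n_nodes < 2:
        raise ValueError("need >= 2 nodes")
    return g.degrees() / g.n_nodes


def nodal_strength(g: BrainGraph) -> np.ndarray:
    """Sum of incident edge weights per node, divided by the node count N."""
    if g.n_nodes < 2:
        raise ValueError("need >= 2 nodes")
    return g.strengths() / g.n_nodes


def clustering_coefficients(g: BrainGraph) -> np.ndarray:
    """Weighted clustering coefficient per node (cube-root triangle form).

    C_i = 2 t_i / (k_i (k_i - 1)) with
    t_i = 1/2 * sum_{j,h} (w_ij w_ih w_jh)^{1/3}; C_i = 0 for k_i < 2.
    With weights in [0, 1] no re-normalization is needed and C_i stays in
    [0, 1].
    """
    a = g.adjacency
    if np.any(a > 1):
        raise ValueError("weights must lie in [0, 1]")
    w3 = np.cbrt(a)
    # diagonal of w3^3 counts each triangle through i twice = 2 t_i
    two_t = np.diag(w3 @ w3 @ w3)
    k = g.degrees().astype(float)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, two_t / denom, 0.0)
    return c


def _inverse_distances(g: BrainGraph) -> np.ndarray:
    """Matrix of 1/d_ij (0 on the diagonal and for disconnected pairs)."""
    a = g.adjacency
    n = g.n_nodes
    with np.errstate(divide="ignore"):
        lengths = np.where(a > 0, 1.0 / a, 0.0)
    d = dijkstra(csr_matrix(lengths), directed=False)
    inv = np.zeros_like(d)
    finite = np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    np.fill_diagonal(inv, 0.0)
    return inv


def efficiency_contributions(g: BrainGraph) -> np.ndarray:
    """Per-node efficiency: mean inverse shortest-path length to all others.

    Edge lengths are inverse weights; disconnected pairs contribute 0.
    The mean of this vector is the network's global efficiency.
    """
    if g.n_nodes < 2:
        raise ValueError("need >= 2 nodes")
    inv = _inverse_distances(g)
    return inv.sum(axis=1) / (g.n_nodes - 1)


def global_efficiency(g: BrainGraph) -> float:
    """Average inverse shortest-path length over all ordered node pairs."""
    return float(np.mean(efficiency_contributions(g)))


def compute_nodal_metrics(g: BrainGraph) -> NodalMetrics:
    return NodalMetrics(
        node_names=list(g.node_names),
        degree_norm=nodal_degree(g),
        strength_norm=nodal_strength(g),
        clustering=clustering_coefficients(g),
        efficiency=efficiency_contributions(g),
    )
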