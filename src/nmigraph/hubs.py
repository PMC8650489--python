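"""Participation coefficients and the four-way hub taxonomy.

A node is a *hub* when both its degree and its strength are at least one
sample standard deviation above the network mean.  Non-hub nodes in the
top 30% for both degree and strength are *high-influence* nodes.  Hubs
whose participation coefficient reaches at least 90% of the network's
theoretical maximum (1 - 1/M for M modules) are *connector* hubs; the
remaining hubs are *provincial*.  Everything else is *other*.  The four
classes are exhaustive and disjoint.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .community import ModularPartition
from .netbuild import BrainGraph

__all__ = ["participation_coefficients", "classify_nodes", "hub_overlap"]


def participation_coefficients(g: BrainGraph, partition) -> np.ndarray:
    """pc_i = 1 - sum_m (k_im / k_i)^2 over binary edge counts per module.

    k_im is the number of edges from node i into module m.  pc is 0 when
    all of a node's edges stay in one module (and for isolated nodes) and
    approaches 1 - 1/M when edges spread evenly over the M modules.
    """
    labels = partition.affiliation if isinstance(partition, ModularPartition) \
        else np.asarray(partition, dtype=np.int64)
    if labels.size != g.n_nodes:
        raise ValueError("partition must cover all nodes")
    a = (g.adjacency > 0).astype(float)
    n_mod = int(labels.max())
    ind = np.zeros((g.n_nodes, n_mod))
    ind[np.arange(g.n_nodes), labels - 1] = 1.0
    k_im = a @ ind
    k = a.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pc = np.where(k > 0, 1.0 - ((k_im / k[:, None]) ** 2).sum(axis=1), 0.0)
    return pc


def _min_ranks_desc(x: np.ndarray) -> np.ndarray:
    """Descending rank (1 = largest); ties share the minimum rank."""
    order = np.sort(x)[::-1]
    return np.searchsorted(-order, -x, side="left") + 1


def classify_nodes(g: BrainGraph, partition) -> pd.DataFrame:
    """HubTable: per-node metrics and hub class.

    Columns: node, module, degree_norm, strength_norm, pc, hub_class with
    hub_class in {connector, provincial, high_influence, other}.

    Thresholds use the sample SD (ddof=1) over nodes of this network and
    ">=" comparisons.  The top-30% selection is min-rank based; when ties
    push more than ceil(0.3 N) nodes past the cutoff, the selection is
    truncated to ceil(0.3 N) by node order for determinism.  With a single
    module the theoretical maximum pc is 0, so every hub degenerates to
    provincial (flagged with a warning).
    """
    n = g.n_nodes
    if n < 3:
        raise ValueError("need >= 3 nodes to classify hubs")
    labels = partition.affiliation if isinstance(partition, ModularPartition) \
        else np.asarray(partition, dtype=np.int64)
    k = g.degrees().astype(float)
    s = g.strengths()
    pc = participation_coefficients(g, labels)
    n_mod = int(labels.max())

    k_sd = k.std(ddof=1)
    s_sd = s.std(ddof=1)
    # a metric in which all nodes tie (sd = 0) singles out nobody
    hub = ((k >= k.mean() + k_sd) & (k_sd > 0)
           & (s >= s.mean() + s_sd) & (s_sd > 0))

    m_top = int(np.ceil(0.3 * n))
    eligible = (~hub) & (_min_ranks_desc(k) <= m_top) & (_min_ranks_desc(s) <= m_top)
    if eligible.sum() > m_top:
        idx = np.flatnonzero(eligible)
        eligible = np.zeros(n, dtype=bool)
        eligible[idx[:m_top]] = True

    if n_mod == 1:
        if hub.any():
            warnings.warn("single-module partition: theoretical maximum pc is 0, "
                          "all hubs classified provincial", stacklevel=2)
        connector = np.zeros(n, dtype=bool)
    else:
        pc_max = 1.0 - 1.0 / n_mod
        connector = hub & (pc >= 0.9 * pc_max)

    hub_class = np.full(n, "other", dtype=object)
    hub_class[eligible] = "high_influence"
    hub_class[hub & ~connector] = "provincial"
    hub_class[connector] = "connector"

    return pd.DataFrame({
        "node": list(g.node_names),
        "module": labels,
        "degree_norm": k / n,
        "strength_norm": s / n,
        "pc": pc,
        "hub_class": hub_class,
    })


def hub_overlap(table_a: pd.DataFrame, table_b: pd.DataFrame) -> dict:
    """Shared/gained/lost hubs between two networks' hub tables."""
    def hubs(t):
        return set(t.loc[t.hub_class.isin(["connector", "provincial"]), "node"])
    a, b = hubs(table_a), hubs(table_b)
    return {
        "shared": sorted(a & b),
        "only_first": sorted(a - b),
        "only_second": sorted(b - a),
        "n_hubs_first": len(a),
        "n_hubs_second": len(b),
    }
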