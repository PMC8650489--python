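"""Thresholding, nodal elimination, group reduction and averaging."""

import numpy as np
import pytest

from nmigraph import (BrainGraph, eliminate_sparse_nodes, graph_density,
                      group_average_network, reduce_to_common_nodes,
                      threshold_to_density)
from conftest import graph_from_edges, random_graph


class TestGraphDensity:
    def test_complete_graph(self):
        g = graph_from_edges(4, [(i, j, 1.0) for i in range(4) for j in range(i + 1, 4)])
        assert graph_density(g) == 1.0

    def test_edgeless_graph(self):
        assert graph_density(BrainGraph(np.zeros((4, 4)), list("abcd"))) == 0.0

    def test_five_of_ten(self):
        g = graph_from_edges(5, [(0, 1, .5), (1, 2, .5), (2, 3, .5), (3, 4, .5), (4, 0, .5)])
        assert graph_density(g) == 0.5


class TestThresholdToDensity:
    def test_dense_212_node_graph_hits_half_density(self):
        rng = np.random.default_rng(0)
        n = 212
        full = np.zeros((n, n))
        full[np.triu_indices(n, 1)] = rng.permutation(np.linspace(0.01, 0.99, n * (n - 1) // 2))
        full = full + full.T
        g = BrainGraph(full, [f"n{i}" for i in range(n)])
        out = threshold_to_density(g)
        assert out.n_edges == 11183
        assert graph_density(out) == 0.5

    def test_below_target_untouched(self):
        g = random_graph(1, n=10, density=0.3)
        out = threshold_to_density(g, 0.9)
        assert np.array_equal(out.adjacency, g.adjacency)

    def test_keeps_three_largest_of_six(self):
        edges = [(0, 1, 0.1), (0, 2, 0.2), (0, 3, 0.3),
                 (1, 2, 0.4), (1, 3, 0.5), (2, 3, 0.6)]
        out = threshold_to_density(graph_from_edges(4, edges), 0.5)
        kept = sorted(out.adjacency[np.triu_indices(4, 1)][
            out.adjacency[np.triu_indices(4, 1)] > 0])
        assert kept == [0.4, 0.5, 0.6]

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent(self, seed):
        g = random_graph(seed, n=15, density=0.9)
        once = threshold_to_density(g, 0.5)
        twice = threshold_to_density(once, 0.5)
        assert np.array_equal(once.adjacency, twice.adjacency)

    @pytest.mark.parametrize("seed", range(20))
    def test_retains_exactly_top_k_by_weight(self, seed):
        g = random_graph(seed, n=12, density=0.95)
        iu = np.triu_indices(12, 1)
        weights = g.adjacency[iu]
        present = weights[weights > 0]
        k = int(np.floor(0.5 * len(iu[0])))
        expected = set(np.sort(present)[::-1][:k])  # weights distinct a.s.
        out = threshold_to_density(g, 0.5)
        got = set(out.adjacency[iu][out.adjacency[iu] > 0])
        assert got == expected

    def test_tie_break_removes_lexicographically_smaller_pair(self):
        edges = [(0, 1, 0.5), (0, 2, 0.5), (1, 2, 0.9)]
        out = threshold_to_density(graph_from_edges(3, edges), 2 / 3)
        assert out.adjacency[0, 1] == 0.0       # (0,1) removed before (0,2)
        assert out.adjacency[0, 2] == 0.5


class TestEliminateSparseNodes:
    def test_star_leaves_meet_five_percent(self):
        # K_{1,19}: leaves have degree 1 of 19 possible = 5.3% >= 5%
        g = graph_from_edges(20, [(0, i, 1.0) for i in range(1, 20)])
        out = eliminate_sparse_nodes(g, 0.05)
        assert out.n_nodes == 20

    def test_isolated_node_removed(self):
        g = graph_from_edges(3, [(0, 1, 0.5)])
        out = eliminate_sparse_nodes(g, 0.0)
        assert out.node_names == ["n00", "n01"]

    def test_zero_fraction_only_drops_disconnected(self):
        g = graph_from_edges(4, [(0, 1, 0.5), (1, 2, 0.5)])
        assert eliminate_sparse_nodes(g, 0.0).n_nodes == 3

    def test_strict_inequality_at_threshold(self):
        # node of degree exactly min_frac*(N-1) is kept
        g = graph_from_edges(21, [(0, i, 1.0) for i in range(1, 21)])
        # leaves: degree 1; threshold 0.05*20 = 1.0 -> 1 >= 1.0 kept
        assert eliminate_sparse_nodes(g, 0.05).n_nodes == 21

    @pytest.mark.parametrize("seed", range(20))
    def test_rerun_removes_nothing_new(self, seed):
        g = threshold_to_density(random_graph(seed, n=20, density=0.4), 0.3)
        once = eliminate_sparse_nodes(g, 0.05)
        twice = eliminate_sparse_nodes(once, 0.05)
        # a second pass may only act through disconnection cascades
        assert set(twice.node_names) <= set(once.node_names)


class TestReduceToCommonNodes:
    def test_identical_sets_unchanged(self):
        gs = [random_graph(0, 6), random_graph(1, 6)]
        out = reduce_to_common_nodes(gs)
        assert out[0].node_names == gs[0].node_names

    def test_set_intersection(self):
        g1 = graph_from_edges(3, [(0, 1, .5), (1, 2, .5)], names=["A", "B", "C"])
        g2 = graph_from_edges(3, [(0, 1, .5), (1, 2, .5)], names=["B", "C", "D"])
        out = reduce_to_common_nodes([g1, g2])
        assert out[0].node_names == ["B", "C"]
        assert out[1].node_names == ["B", "C"]

    def test_matches_brute_force_set_oracle(self):
        rng = np.random.default_rng(3)
        graphs, names_sets = [], []
        for s in range(3):
            g = random_graph(s, n=12, density=0.6)
            keep = np.sort(rng.choice(12, size=9, replace=False))
            graphs.append(g.subgraph(keep))
            names_sets.append(set(graphs[-1].node_names))
        expected = names_sets[0] & names_sets[1] & names_sets[2]
        out = reduce_to_common_nodes(graphs)
        assert set(out[0].node_names) == expected

    def test_empty_intersection_is_error(self):
        g1 = graph_from_edges(2, [(0, 1, .5)], names=["A", "B"])
        g2 = graph_from_edges(2, [(0, 1, .5)], names=["C", "D"])
        with pytest.raises(ValueError, match="empty"):
            reduce_to_common_nodes([g1, g2])


class TestGroupAverageNetwork:
    def test_single_graph_at_target_is_identity(self):
        g = threshold_to_density(random_graph(2, n=10, density=0.9), 0.5)
        out = group_average_network([g], 0.5)
        assert np.array_equal(out.adjacency, g.adjacency)

    def test_disjoint_supports_halve_then_cut(self):
        g1 = graph_from_edges(4, [(0, 1, 0.8), (2, 3, 0.6)])
        g2 = graph_from_edges(4, [(0, 2, 0.4), (1, 3, 0.2)])
        out = group_average_network([g1, g2], 0.5)
        # averaged weights: 0.4, 0.3, 0.2, 0.1 on 4 edges; keep top 3 of 6*0.5
        iu = np.triu_indices(4, 1)
        kept = np.sort(out.adjacency[iu][out.adjacency[iu] > 0])
        assert np.allclose(kept, [0.2, 0.3, 0.4])

    def test_group_network_density_exactly_half(self):
        graphs = [threshold_to_density(random_graph(s, n=30, density=1.0), 0.5)
                  for s in range(5)]
        out = group_average_network(graphs, 0.5)
        assert graph_density(out) == pytest.approx(
            np.floor(0.5 * 435) / 435, abs=0)

    def test_mismatched_node_sets_rejected(self):
        g1 = graph_from_edges(2, [(0, 1, .5)], names=["A", "B"])
        g2 = graph_from_edges(2, [(0, 1, .5)], names=["A", "C"])
        with pytest.raises(ValueError, match="node set"):
            group_average_network([g1, g2])
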