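import numpy as np
import pytest

from nmigraph import BrainGraph


def random_graph(seed: int, n: int = 10, density: float = 0.5) -> BrainGraph:
    """Random weighted undirected graph with distinct weights in (0, 1)."""
    rng = np.random.default_rng(seed)
    a = np.triu(rng.random((n, n)) * (rng.random((n, n)) < density), 1)
    a = a + a.T
    return BrainGraph(adjacency=a, node_names=[f"n{i:02d}" for i in range(n)])


def graph_from_edges(n: int, edges, names=None) -> BrainGraph:
    a = np.zeros((n, n))
    for i, j, w in edges:
        a[i, j] = a[j, i] = w
    return BrainGraph(adjacency=a,
                      node_names=names or [f"n{i:02d}" for i in range(n)])


@pytest.fixture
def two_triangles() -> BrainGraph:
    """Two disconnected unit-weight triangles (known optimal Q = 0.5)."""
    edges = [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0),
             (3, 4, 1.0), (4, 5, 1.0), (3, 5, 1.0)]
    return graph_from_edges(6, edges)
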