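import numpy as np
import pytest
import scipy.sparse as sp

from spotsbm import ExpressionMatrix, MultiLayerGraph, SpatialCoords


def graph_from_edges(n, *layer_edges):
    """Build a MultiLayerGraph from 0-based undirected edge lists."""
    layers = []
    for edges in layer_edges:
        a = np.zeros((n, n), dtype=np.int8)
        for i, j in edges:
            a[i, j] = a[j, i] = 1
        layers.append(sp.csr_matrix(a))
    return MultiLayerGraph(layers=layers)


def random_multilayer(n, n_layers=2, p=0.4, seed=0):
    rng = np.random.default_rng(seed)
    layers = []
    for _ in range(n_layers):
        u = np.triu(rng.random((n, n)) < p, k=1)
        layers.append(sp.csr_matrix((u | u.T).astype(np.int8)))
    return MultiLayerGraph(layers=layers)


@pytest.fixture
def toy_pair_graph():
    """Hand-counted two-layer, four-node graph with labels (1,1,2,2):
    layer 1 edges {0,1},{2,3},{0,2}; layer 2 edges {0,1},{2,3}."""
    g = graph_from_edges(4, [(0, 1), (2, 3), (0, 2)], [(0, 1), (2, 3)])
    z = np.array([1, 1, 2, 2])
    return g, z


@pytest.fixture
def toy_expression():
    rng = np.random.default_rng(42)
    counts = rng.poisson(5.0, size=(12, 6)).astype(float)
    return ExpressionMatrix(
        counts=counts,
        spot_ids=[f"s{i}" for i in range(12)],
        gene_ids=[f"g{j}" for j in range(6)],
    )


@pytest.fixture
def toy_coords():
    rng = np.random.default_rng(43)
    return SpatialCoords(
        xy=rng.normal(size=(12, 2)), spot_ids=[f"s{i}" for i in range(12)]
    )
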