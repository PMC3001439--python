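import numpy as np
import pytest

from etadiffuse import (
    LabelTable,
    PlantedConfig,
    SimilarityNetwork,
    build_network,
    bridge_cluster_fixture,
    planted_function_network,
)
from etadiffuse.match_graph import EdgeData


def network_from_edges(nodes, weighted_edges):
    """Hand-built network: {(a, b): weight} with dummy provenance."""
    edges = {
        tuple(sorted(pair)): EdgeData(weight=w, avg_rmsd=1.0, avg_et=1.0)
        for pair, w in weighted_edges.items()
    }
    return SimilarityNetwork(nodes=list(nodes), edges=edges)


def random_network(rng, n_nodes, p_edge=0.3):
    """Random weighted graph for solver-oracle comparisons."""
    nodes = [f"n{i:03d}" for i in range(n_nodes)]
    edges = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                edges[(nodes[i], nodes[j])] = float(rng.uniform(0.05, 1.0))
    return network_from_edges(nodes, edges)


@pytest.fixture(scope="session")
def bridge():
    """Fig-6-style bridge dataset plus its built network."""
    dataset = bridge_cluster_fixture()
    return dataset, build_network(dataset.records)


@pytest.fixture(scope="session")
def planted_small():
    """A small, quick planted benchmark (3 functions x 12 nodes)."""
    cfg = PlantedConfig(n_functions=3, nodes_per_function=12, p_in=0.5,
                        p_out=0.02, seed=11)
    dataset = planted_function_network(cfg)
    return dataset, build_network(dataset.records)


@pytest.fixture
def two_cluster_flip():
    """Frozen 6-node fixture where negative labels flip the query's call.

    The query sits between two labeled clusters, tied more strongly to the
    second; competitive diffusion without negative labels follows that
    local pull, with negative labels the call flips.
    """
    nodes = ["a1", "a2", "b1", "b2", "q", "u"]
    weights = {
        ("a1", "a2"): 0.5,
        ("a1", "q"): 0.5,
        ("a1", "u"): 0.3,
        ("a2", "b1"): 0.9,
        ("b2", "q"): 0.9,
        ("b2", "u"): 0.9,
    }
    labels = LabelTable({
        "a1": ["1.1.1.1"], "a2": ["1.1.1.1"],
        "b1": ["2.1.1.1"], "b2": ["2.1.1.1"],
    })
    return network_from_edges(nodes, weights), labels


def dense_diffusion(network, y, alpha, rng=None):
    """Independent dense oracle: numpy solve of (I + alpha*(D - W)) f = y."""
    W = network.adjacency().toarray()
    L = np.diag(W.sum(axis=1)) - W
    A = np.eye(network.n_nodes) + alpha * L
    return np.linalg.solve(A, y)
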