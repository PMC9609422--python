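from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from netpharm import PPINetwork, SyntheticConfig, PlantedModule


def net_from(edges, nodes=()):
    """Build a PPINetwork from (a, b[, confidence]) tuples."""
    triples = [
        (e[0], e[1], e[2] if len(e) > 2 else 1.0) for e in edges
    ]
    net = PPINetwork.from_edges(triples)
    net.graph.add_nodes_from(nodes)
    return net


def random_net(rng: np.random.Generator, n: int, p: float) -> PPINetwork:
    """Erdos-Renyi network with unit confidences (test scaffolding)."""
    g = nx.Graph()
    names = [f"N{i:03d}" for i in range(n)]
    g.add_nodes_from(names)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(names[i], names[j], confidence=1.0)
    return PPINetwork(g)


def adjacency(net: PPINetwork) -> dict[str, set[str]]:
    return {v: set(net.graph.neighbors(v)) for v in net.graph.nodes}


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_cfg():
    """Down-scaled generation regime for fast unit tests."""
    return SyntheticConfig(
        seed=11,
        n_nodes=150,
        target_edges=700,
        planted_modules=[PlantedModule(12, 1.0), PlantedModule(10, 0.8)],
        disease_list_size=60,
        target_list_size=30,
        overlap_count=10,
        n_terms=12,
        term_size_range=(8, 30),
        query_size=40,
    )


@pytest.fixture
def sparse_clique_cfg():
    """Planted cliques on a background too sparse to score (degree < 4)."""
    return SyntheticConfig(
        seed=5,
        n_nodes=200,
        target_edges=139 + 200,
        planted_modules=[
            PlantedModule(8, 1.0),
            PlantedModule(10, 1.0),
            PlantedModule(12, 1.0),
        ],
        disease_list_size=80,
        target_list_size=40,
        overlap_count=15,
    )
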