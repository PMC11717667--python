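import itertools

import networkx as nx
import numpy as np
import pytest

from xtrait.io import InteractionNetwork, TargetSet


def clique_edges(prefix: str, n: int):
    return [(f"{prefix}{i}", f"{prefix}{j}") for i, j in itertools.combinations(range(n), 2)]


@pytest.fixture
def path_graph():
    """Path a-b-c-d-e."""
    return InteractionNetwork.from_edges(
        [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]
    )


@pytest.fixture
def k5_k4_bridge():
    """Two cliques K5 and K4 joined by a single bridge edge a0-b0."""
    edges = clique_edges("a", 5) + clique_edges("b", 4) + [("a0", "b0")]
    return InteractionNetwork.from_edges(edges)


@pytest.fixture
def two_triangles_bridged():
    """Triangles pqr and uvw joined by the edge r-u."""
    return InteractionNetwork.from_edges(
        [("p", "q"), ("q", "r"), ("p", "r"),
         ("u", "v"), ("v", "w"), ("u", "w"), ("r", "u")]
    )


def random_network(rng: np.random.Generator, n: int, p: float) -> InteractionNetwork:
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    net = InteractionNetwork(nx.Graph(), name="rand")
    net.graph.add_nodes_from(g.nodes)
    for a, b in g.edges:
        net.graph.add_edge(a, b, weight=1.0)
    return net


def random_target_set(rng: np.random.Generator, net: InteractionNetwork, size: int, name: str) -> TargetSet:
    nodes = sorted(net.graph.nodes)
    picks = rng.choice(nodes, size=min(size, len(nodes)), replace=False)
    return TargetSet(name, tuple(picks))
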