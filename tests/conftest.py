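import random

import pytest

from ppiscreen import InteractionNetwork


def net_from_edges(edges, extra_nodes=()):
    net = InteractionNetwork()
    for a, b in edges:
        net.add_edge(a, b)
    for v in extra_nodes:
        net.add_node(v)
    return net


def random_network(rng: random.Random, n: int, p: float) -> InteractionNetwork:
    """G(n, p) over labels N00..; may be disconnected or have isolated nodes."""
    nodes = [f"N{i:02d}" for i in range(n)]
    net = InteractionNetwork()
    for v in nodes:
        net.add_node(v)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(nodes[i], nodes[j])
    return net


def path_graph(*names):
    return net_from_edges(zip(names, names[1:]))


def star_graph(m: int, center: str = "C") -> InteractionNetwork:
    return net_from_edges((center, f"L{i:02d}") for i in range(m))


def complete_graph(n: int) -> InteractionNetwork:
    nodes = [f"K{i:02d}" for i in range(n)]
    return net_from_edges(
        (nodes[i], nodes[j]) for i in range(n) for j in range(i + 1, n)
    )


@pytest.fixture
def paper_hubs():
    # the ten top-degree genes reported for the CRC network
    return (
        "SRC", "EGFR", "CTNNB1", "CDH1", "IL8",
        "PCNA", "TIMP1", "HSPD1", "PTPRC", "SERPINA1",
    )


@pytest.fixture
def paper_bottlenecks():
    # the ten top-betweenness genes reported for the CRC network
    return (
        "SRC", "EGFR", "PCNA", "IL8", "CTNNB1",
        "TIMP1", "HSPB1", "CDH1", "SPTAN1", "HSPD1",
    )
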