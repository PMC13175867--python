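import networkx as nx
import pytest

from lncprox.interactome import Interactome


@pytest.fixture
def path_graph():
    """A - B - C path."""
    return Interactome([("A", "B"), ("B", "C")])


@pytest.fixture
def star_graph():
    return Interactome([("X", f"L{i}") for i in range(5)])


@pytest.fixture
def two_components():
    return Interactome([("A", "B"), ("B", "C"), ("D", "E")])


def random_connected_graph(n, rng):
    """Small connected graph: random tree plus extra random edges."""
    g = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
    extra = rng.integers(0, n)
    nodes = list(g.nodes)
    for _ in range(int(extra)):
        a, b = rng.choice(nodes, size=2, replace=False)
        if a != b:
            g.add_edge(a, b)
    return Interactome.from_nx(nx.relabel_nodes(g, {u: f"n{u}" for u in g.nodes}))
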