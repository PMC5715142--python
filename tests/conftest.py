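import hypothesis
import networkx as nx
import pytest

hypothesis.settings.register_profile("deterministic", derandomize=True)
hypothesis.settings.load_profile("deterministic")


def graph_from_edges(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


@pytest.fixture
def k5_with_pendant():
    """A 5-clique plus one pendant vertex hanging off n0."""
    g = nx.complete_graph(5)
    g.add_edge(0, 5)
    return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
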