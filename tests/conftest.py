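import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from ppicohort import Interactome, SampleGraph

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_interactome(edges):
    """Interactome from (u, v, confidence) triples."""
    g = nx.Graph()
    for u, v, conf in edges:
        g.add_edge(u, v, confidence=conf)
    return Interactome(g)


def make_sample_graph(sample, nodes, edges=None):
    """SampleGraph with the given node set; default edges chain the
    sorted nodes (confidence 1.0, all seeds)."""
    g = nx.Graph()
    nodes = sorted(nodes)
    g.add_nodes_from(nodes, role="seed")
    if edges is None:
        edges = list(zip(nodes, nodes[1:]))
    for u, v in edges:
        g.add_edge(u, v, confidence=1.0)
    return SampleGraph(sample=sample, graph=g)


@pytest.fixture
def path_interactome():
    """Path graph a-b-c-d-e, all confidences 1.0."""
    return make_interactome(
        [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0), ("d", "e", 1.0)]
    )
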