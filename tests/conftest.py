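import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from hetpath.embedding import diffusion_states, mashup_embed
from hetpath.net_builder import CHEMICAL, ENZYME, HeteroNetwork
from hetpath.synthfix import make_benchmark

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def net_from_edges(edges, kinds):
    """Build a HeteroNetwork from (u, v, weight) triples and a kind map."""
    g = nx.Graph()
    for node, kind in kinds.items():
        g.add_node(node, kind=kind)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return HeteroNetwork(g)


@pytest.fixture
def two_node_net():
    return net_from_edges([("a", "b", 0.8)], {"a": CHEMICAL, "b": CHEMICAL})


@pytest.fixture
def path_net():
    # chain a-b-c with weights 0.2 and 0.8
    return net_from_edges(
        [("a", "b", 0.2), ("b", "c", 0.8)],
        {"a": CHEMICAL, "b": CHEMICAL, "c": ENZYME},
    )


@pytest.fixture
def triangle_net():
    return net_from_edges(
        [("a", "b", 0.4), ("b", "c", 0.4), ("a", "c", 0.4)],
        {"a": CHEMICAL, "b": CHEMICAL, "c": CHEMICAL},
    )


@pytest.fixture(scope="session")
def easy_benchmark():
    """The default easy synthetic benchmark (180 nodes, 5 labels)."""
    return make_benchmark("easy")


@pytest.fixture(scope="session")
def easy_features(easy_benchmark):
    """32-dimensional embedding of the easy benchmark."""
    states = diffusion_states(easy_benchmark.network)
    return mashup_embed(states, d=32).X
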