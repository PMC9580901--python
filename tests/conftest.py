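import io

import networkx as nx
import pytest

from adrnet.graphio import InteractomeGraph, load_interactome
from adrnet.propagation import SeedSet
from adrnet.synth import SynthConfig, generate_fixture


def graph_from_edges(edges, extra_nodes=()):
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(extra_nodes)
    return InteractomeGraph(graph=g)


@pytest.fixture
def path3():
    """P1 - P2 - P3"""
    return graph_from_edges([("P1", "P2"), ("P2", "P3")])


@pytest.fixture
def triangle():
    return graph_from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def cycle4():
    return graph_from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])


@pytest.fixture
def two_triangles_bridge():
    """Two triangles {a,b,c} and {x,y,z} joined by the single edge c-x."""
    return graph_from_edges(
        [
            ("a", "b"), ("b", "c"), ("a", "c"),
            ("x", "y"), ("y", "z"), ("x", "z"),
            ("c", "x"),
        ]
    )


@pytest.fixture
def two_node():
    return graph_from_edges([("a", "b")])


def load_edges(text, **kw):
    return load_interactome(io.StringIO(text), **kw)


@pytest.fixture(scope="session")
def small_fixture():
    """A 300-node synthetic fixture shared by slower integration tests."""
    cfg = SynthConfig(
        n_nodes=300,
        attachment_m=3,
        module_size=20,
        densify_prob=0.3,
        panel_size=20,
        rng_seed=11,
    )
    return generate_fixture(cfg)


@pytest.fixture
def seeds_ab():
    return SeedSet(adr_label="test adr", accessions={"a", "b"})
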