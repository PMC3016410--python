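import networkx as nx
import numpy as np
import pytest

from petals.formats_io import OBSERVED, ExpressionBundle
from petals.synthetic_fixtures import FixtureSpec, generate_fixture


def make_network(edges, counts=None):
    graph = nx.Graph()
    for i, (u, v) in enumerate(edges):
        count = counts[i] if counts else 1
        graph.add_edge(u, v, observation_count=count, provenance=OBSERVED)
    return graph


@pytest.fixture
def triangle():
    return make_network([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def star():
    return make_network([("hub", "x"), ("hub", "y"), ("hub", "z")])


@pytest.fixture
def small_expression():
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{i}" for i in range(8)]
    values = rng.standard_normal((6, 8))
    groups = ["WT"] * 4 + ["MT"] * 4
    return ExpressionBundle(genes=genes, samples=samples, values=values, groups=groups)


@pytest.fixture(scope="session")
def default_bundle():
    """One shared desk-scale fixture; treat as read-only."""
    return generate_fixture(FixtureSpec(seed=20260905))
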