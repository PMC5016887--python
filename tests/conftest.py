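import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cimds.graph_core import make_network
from cimds.synth_fixtures import FixtureSpec, random_network


@pytest.fixture
def path4():
    """Path a-b-c-d."""
    return make_network([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def star5():
    """Star: centre c with 4 leaves."""
    return make_network([("c", f"l{i}") for i in range(1, 5)])


@pytest.fixture
def cycle4():
    return make_network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])


def seeded_graphs(n_graphs, n_min=5, n_max=12, p=0.35, seed0=100):
    """A reproducible ensemble of small ER graphs (singletons allowed)."""
    out = []
    for i in range(n_graphs):
        spec = FixtureSpec(seed=seed0 + i, n_nodes=n_min + i % (n_max - n_min + 1),
                           edge_prob=p)
        out.append(random_network(spec))
    return out


@pytest.fixture(scope="session")
def small_ensemble():
    return seeded_graphs(30)
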