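import itertools

import numpy as np
import pytest

from loctom import MAJOR_LOCATIONS, LocalizationTable, Network
from loctom.synthetic import fig2_fixture


@pytest.fixture
def fig2():
    """The five-protein toy network with its location annotation."""
    return fig2_fixture()


@pytest.fixture
def triangle():
    return Network.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


def random_network(rng: np.random.Generator, n: int, p: float) -> Network:
    """Erdos-Renyi network over n labeled nodes."""
    ids = [f"n{i:03d}" for i in range(n)]
    net = Network()
    for i in ids:
        net.add_node(i)
    for u, v in itertools.combinations(ids, 2):
        if rng.random() < p:
            net.add_edge(u, v)
    return net


def random_localization(rng: np.random.Generator, nodes, max_labels: int = 3) -> LocalizationTable:
    """Random 1..max_labels major locations per node."""
    entries = {}
    for n in nodes:
        k = int(rng.integers(1, max_labels + 1))
        entries[n] = frozenset(rng.choice(MAJOR_LOCATIONS, size=k, replace=False))
    return LocalizationTable(entries)
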