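import numpy as np
import pytest

from nmaudit.datamodel import ComparisonKey
from nmaudit.effects import Contrast


@pytest.fixture
def chain_contrasts():
    """A-B (est 2, se 1) and B-C (est 5, se 1): indirect A:C = 7, se sqrt(2)."""
    return [
        Contrast("t1", ComparisonKey("A", "B"), 2.0, 1.0),
        Contrast("t2", ComparisonKey("B", "C"), 5.0, 1.0),
    ]


@pytest.fixture
def triangle_contrasts(chain_contrasts):
    """Chain plus a coherent direct A:C trial (est 7, se 1)."""
    return chain_contrasts + [Contrast("t3", ComparisonKey("A", "C"), 7.0, 1.0)]


@pytest.fixture
def incoherent_triangle(chain_contrasts):
    """Chain implying A:C = 7 plus a direct A:C trial at 0 (se 0.5)."""
    return chain_contrasts + [Contrast("t3", ComparisonKey("A", "C"), 0.0, 0.5)]


def random_two_arm_network(rng: np.random.Generator, n_nodes: int, n_trials: int):
    """Random connected two-arm-trial contrast set over n_nodes labels."""
    import networkx as nx

    nodes = [chr(ord("A") + i) for i in range(n_nodes)]
    while True:
        contrasts = []
        for t in range(n_trials):
            a, b = rng.choice(n_nodes, size=2, replace=False)
            contrasts.append(
                Contrast(
                    f"t{t}",
                    ComparisonKey(nodes[a], nodes[b]),
                    float(rng.normal(0, 3)),
                    float(rng.uniform(0.5, 2.0)),
                )
            )
        g = nx.Graph((c.pair.a, c.pair.b) for c in contrasts)
        if len(g.nodes) == n_nodes and nx.is_connected(g):
            return contrasts
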