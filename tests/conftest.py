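import numpy as np
import pytest

from signpred.model import ObservationSet, Sign, SignedInteractionGraph
from signpred.synthetic import fixture_library


@pytest.fixture(scope="session")
def fixtures():
    return fixture_library()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_graph(edges, nodes=()):
    """Build a SignedInteractionGraph from (source, sign_char, target) triples."""
    g = SignedInteractionGraph()
    for n in nodes:
        g.add_node(n)
    for u, s, v in edges:
        g.add_edge(u, v, Sign.from_str(s))
    return g


def obs(**kwargs):
    return ObservationSet({k: Sign.from_str(v) for k, v in kwargs.items()})


def random_protein_graph(rng, n, inhibition=0.3, edge_factor=2):
    """Arbitrary signed digraph on n protein nodes (cycles allowed)."""
    g = SignedInteractionGraph()
    names = [f"N{i}_prot" for i in range(n)]
    for nm in names:
        g.add_node(nm)
    for _ in range(int(rng.integers(n, edge_factor * n + 1))):
        u, v = rng.choice(n, 2, replace=False)
        g.add_edge(names[u], names[v], Sign.MINUS if rng.random() < inhibition else Sign.PLUS)
    return g


def random_observations(rng, graph, k):
    nodes = rng.choice(graph.node_ids(), size=k, replace=False)
    return ObservationSet(
        {str(n): (Sign.PLUS if rng.random() < 0.5 else Sign.MINUS) for n in nodes}
    )
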