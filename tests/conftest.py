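import networkx as nx
import numpy as np
import pytest

from netpharm.library import CompoundRecord, FormulaLibrary
from netpharm.synth import SynthConfig, generate_bundle, load_fixtures


@pytest.fixture(scope="session")
def table5():
    return load_fixtures("table5")


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic bundle shared across tests."""
    return generate_bundle(SynthConfig(seed=42))


@pytest.fixture
def tiny_library():
    """Hand-built 6-compound, 2-herb library exercising all flags."""
    recs = [
        CompoundRecord("A1", "alpha", frozenset({"H1"}), 78.2),
        CompoundRecord("A2", "beta", frozenset({"H1", "H2"}), 50.0),
        CompoundRecord("A3", "gamma", frozenset({"H2"}), 3.01, abundant=True),
        CompoundRecord("A4", "delta", frozenset({"H2"}), 36.4, designated=True),
        CompoundRecord("A5", "epsilon", frozenset({"H2"}), 6.5,
                       parent_id="A4", designated=True),
        CompoundRecord("A6", "zeta", frozenset({"H1"}), 12.0),
    ]
    return FormulaLibrary(compounds={r.compound_id: r for r in recs})


def random_connected_graph(rng, max_nodes=12):
    """Small random connected graph for centrality oracles."""
    n = int(rng.integers(3, max_nodes + 1))
    p = float(rng.uniform(0.2, 0.7))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
    # stitch components together so betweenness is exercised globally
    comps = [sorted(c) for c in nx.connected_components(g)]
    for a, b in zip(comps, comps[1:]):
        g.add_edge(a[0], b[0])
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(20261002)
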