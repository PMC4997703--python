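import networkx as nx
import numpy as np
import pandas as pd
import pytest

from encentra import SyntheticSpec, attach_missing, edge_correlations, generate


def graph(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


@pytest.fixture
def triangle():
    return graph([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3():
    return graph([("a", "b"), ("b", "c")])


@pytest.fixture
def star4():
    return graph([("hub", leaf) for leaf in "wxyz"])


def random_graph(rng, n_max=7, p=0.4):
    """Small Erdős–Rényi test graph with string node labels."""
    n = int(rng.integers(2, n_max + 1))
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(f"n{i}", f"n{j}")
    return g


def random_correlations(rng, net):
    """Random PCC-like weights in [-1, 1] for every edge of ``net``."""
    from encentra import EdgeCorrelations
    from encentra.coexpression import _edge_key

    return EdgeCorrelations(
        {_edge_key(u, v): float(rng.uniform(-1, 1)) for u, v in net.edges}
    )


@pytest.fixture(scope="session")
def small_spec():
    """A fast, reduced benchmark used where size does not matter."""
    return SyntheticSpec(
        n_proteins=80,
        n_samples=20,
        n_modules=4,
        module_size=4,
        n_decoy_hubs=5,
        decoy_degree=10,
        background_degree=3.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_fixture(small_spec):
    net, expr, ess = generate(small_spec)
    corr = edge_correlations(net, attach_missing(net, expr))
    return net, expr, ess, corr


@pytest.fixture(scope="session")
def study_fixture():
    """The default study conditions, seed 7."""
    net, expr, ess = generate(SyntheticSpec(seed=7))
    corr = edge_correlations(net, attach_missing(net, expr))
    return net, expr, ess, corr


def expr_frame(rows: dict[str, list[float]], samples=None) -> pd.DataFrame:
    first = next(iter(rows.values()))
    cols = samples or [f"S{i}" for i in range(len(first))]
    return pd.DataFrame(
        np.array(list(rows.values()), dtype=float), index=list(rows), columns=cols
    )
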