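import itertools
import math

import networkx as nx
import numpy as np
import pytest

from encentra import (
    betweenness_centrality,
    closeness_centrality,
    degree_centrality,
    eigenvector_centrality,
    subgraph_centrality,
    weighted_centrality,
)
from encentra.coexpression import EdgeCorrelations, _edge_key

from conftest import graph, random_graph

# ---------------------------------------------------------------- oracles


def bfs_distances(net, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in net.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_betweenness(net):
    """Enumerate every simple path; keep the shortest ones per pair."""
    nodes = list(net.nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = list(nx.all_simple_paths(net, s, t))
        if not paths:
            continue
        shortest = min(map(len, paths))
        sp = [p for p in paths if len(p) == shortest]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in sp if v in p)
            score[v] += through / len(sp)
    return score


def brute_closeness(net):
    n = net.number_of_nodes()
    out = {}
    for v in net.nodes:
        dist = bfs_distances(net, v)
        reach = len(dist) - 1
        if reach == 0:
            out[v] = 0.0
        else:
            total = sum(dist.values())
            out[v] = (reach / (n - 1)) * (reach / total)
    return out


def truncated_subgraph(net, kmax=25):
    nodes = list(net.nodes)
    adj = nx.to_numpy_array(net, nodelist=nodes)
    acc = np.eye(len(nodes))
    power = np.eye(len(nodes))
    for k in range(1, kmax + 1):
        power = power @ adj
        acc += power / math.factorial(k)
    return dict(zip(nodes, np.diag(acc)))


def power_iteration_ec(net, tol=1e-15, max_iter=200_000):
    """Power iteration per component; iterates on A + I so bipartite
    components (whose spectrum is symmetric) still converge to the
    Perron vector."""
    comps = [sorted(c) for c in nx.connected_components(net) if len(c) > 1]
    if not comps:
        return {v: 0.0 for v in net.nodes}
    best_nodes, best_lam, best_vec = None, -np.inf, None
    for nodes in comps:
        adj = nx.to_numpy_array(net, nodelist=nodes)
        shifted = adj + np.eye(len(nodes))
        x = np.ones(len(nodes)) / math.sqrt(len(nodes))
        for _ in range(max_iter):
            y = shifted @ x
            y /= np.linalg.norm(y)
            if np.linalg.norm(y - x) < tol:
                x = y
                break
            x = y
        lam = float(x @ adj @ x)
        if lam > best_lam + 1e-12 or (
            abs(lam - best_lam) <= 1e-12 and best_nodes and nodes[0] < best_nodes[0]
        ):
            best_nodes, best_lam, best_vec = nodes, lam, x
    scores = {v: 0.0 for v in net.nodes}
    for v, s in zip(best_nodes, best_vec):
        scores[v] = float(s)
    return scores


def has_unique_dominant_component(net):
    lams = []
    for comp in nx.connected_components(net):
        nodes = sorted(comp)
        if len(nodes) == 1:
            lams.append(0.0)
        else:
            lams.append(float(np.linalg.eigvalsh(nx.to_numpy_array(net, nodelist=nodes))[-1]))
    lams.sort()
    return len(lams) == 1 or lams[-1] - lams[-2] > 1e-9


# -------------------------------------------------------- reference values


class TestClosedForms:
    def test_degree(self, triangle, star4):
        assert degree_centrality(triangle) == {"a": 2, "b": 2, "c": 2}
        dc = degree_centrality(star4)
        assert dc["hub"] == 4 and all(dc[leaf] == 1 for leaf in "wxyz")
        assert degree_centrality(graph([], nodes=["solo"]))["solo"] == 0

    def test_betweenness_path_star_complete(self, path3, star4):
        bc = betweenness_centrality(path3)
        assert bc == {"a": 0.0, "b": 1.0, "c": 0.0}
        bc = betweenness_centrality(star4)
        assert bc["hub"] == pytest.approx(6.0)  # C(4,2) leaf pairs
        assert all(bc[leaf] == 0 for leaf in "wxyz")
        k5 = graph(itertools.combinations("abcde", 2))
        assert all(v == 0 for v in betweenness_centrality(k5).values())

    def test_closeness_values(self, path3):
        cc = closeness_centrality(path3)
        assert cc["b"] == pytest.approx(1.0)
        assert cc["a"] == pytest.approx(2 / 3)
        k2 = graph([("a", "b")])
        assert closeness_centrality(k2) == {"a": 1.0, "b": 1.0}
        iso = graph([], nodes=["solo"])
        assert closeness_centrality(iso)["solo"] == 0.0

    def test_eigenvector_symmetry_and_star_ratio(self, triangle, star4):
        ec = eigenvector_centrality(triangle)
        vals = list(ec.values())
        assert max(vals) == pytest.approx(min(vals))
        assert np.linalg.norm(vals) == pytest.approx(1.0)
        ec = eigenvector_centrality(star4)
        assert ec["hub"] / ec["w"] == pytest.approx(2.0)  # lambda = sqrt(4)
        withiso = graph([("a", "b")], nodes=["solo"])
        assert eigenvector_centrality(withiso)["solo"] == 0.0

    def test_subgraph_closed_forms(self, triangle):
        assert subgraph_centrality(graph([], nodes=["solo"]))["solo"] == pytest.approx(1.0)
        k2 = graph([("a", "b")])
        assert subgraph_centrality(k2)["a"] == pytest.approx(math.cosh(1.0), abs=1e-12)
        sc = subgraph_centrality(triangle)
        expected = (math.e**2 + 2 / math.e) / 3
        assert sc["a"] == pytest.approx(expected, abs=1e-12)


# ------------------------------------------------------------ equivalences


class TestOracleEquivalence:
    def test_random_small_graphs(self):
        rng = np.random.default_rng(2024)
        checked_ec = 0
        for _ in range(200):
            net = random_graph(rng)
            bc = betweenness_centrality(net)
            for v, expected in brute_betweenness(net).items():
                assert bc[v] == pytest.approx(expected, abs=1e-9)
            cc = closeness_centrality(net)
            for v, expected in brute_closeness(net).items():
                assert cc[v] == pytest.approx(expected, abs=1e-12)
            sc = subgraph_centrality(net)
            for v, expected in truncated_subgraph(net).items():
                assert sc[v] == pytest.approx(expected, abs=1e-8)
            if has_unique_dominant_component(net):
                checked_ec += 1
                ec = eigenvector_centrality(net)
                for v, expected in power_iteration_ec(net).items():
                    assert ec[v] == pytest.approx(expected, abs=1e-10)
        assert checked_ec >= 150

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        for measure in (
            degree_centrality,
            betweenness_centrality,
            closeness_centrality,
            eigenvector_centrality,
            subgraph_centrality,
        ):
            net = random_graph(rng, n_max=7)
            mapping = {v: f"renamed_{v}" for v in net.nodes}
            relabeled = nx.relabel_nodes(net, mapping)
            orig = measure(net)
            new = measure(relabeled)
            for v in net.nodes:
                assert new[mapping[v]] == pytest.approx(orig[v], abs=1e-12)

    def test_isolated_node_does_not_disturb_scores(self, star4):
        plus = star4.copy()
        plus.add_node("lonely")
        for measure in (degree_centrality, betweenness_centrality):
            before = measure(star4)
            after = measure(plus)
            for v in star4.nodes:
                assert after[v] == before[v]
        ec_after = eigenvector_centrality(plus)
        assert ec_after["hub"] / ec_after["w"] == pytest.approx(2.0)

    def test_score_bounds(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            net = random_graph(rng)
            assert all(s >= 1.0 - 1e-12 for s in subgraph_centrality(net).values())
            assert all(s >= 0 for s in betweenness_centrality(net).values())
            assert all(0 <= s <= 1 + 1e-12 for s in closeness_centrality(net).values())
            assert all(s >= -1e-12 for s in eigenvector_centrality(net).values())


# ----------------------------------------------------------- weighted forms


def corr_of(net, weight):
    if callable(weight):
        return EdgeCorrelations({_edge_key(u, v): weight(u, v) for u, v in net.edges})
    return EdgeCorrelations({_edge_key(u, v): weight for u, v in net.edges})


class TestWeightedCentrality:
    def test_bc_cc_rejected_with_positive_weight_reason(self, triangle):
        corr = corr_of(triangle, 0.5)
        for m in ("BC", "CC"):
            with pytest.raises(ValueError, match="positive edge weights"):
                weighted_centrality(triangle, corr, m)

    def test_weighted_degree_is_node_strength(self, triangle):
        corr = corr_of(triangle, 0.5)
        wdc = weighted_centrality(triangle, corr, "DC")
        assert all(v == pytest.approx(1.0) for v in wdc.values())

    def test_weighted_sc_of_zero_weights_is_one(self, triangle):
        corr = corr_of(triangle, 0.0)
        wsc = weighted_centrality(triangle, corr, "SC")
        assert all(v == pytest.approx(1.0) for v in wsc.values())

    def test_weighted_ec_matches_shifted_power_iteration(self):
        rng = np.random.default_rng(21)
        net = random_graph(rng, n_max=6, p=0.7)
        corr = corr_of(net, lambda u, v: float(rng.uniform(-1, 1)))
        wec = weighted_centrality(net, corr, "EC")
        nodes = list(net.nodes)
        adj = np.zeros((len(nodes), len(nodes)))
        idx = {v: i for i, v in enumerate(nodes)}
        for u, v in net.edges:
            adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = corr.get(u, v)
        shifted = adj + 2 * len(nodes) * np.eye(len(nodes))  # make top eigenvalue dominant
        x = rng.normal(size=len(nodes))
        for _ in range(20_000):
            y = shifted @ x
            y /= np.linalg.norm(y)
            if np.linalg.norm(y - x) < 1e-15:
                x = y
                break
            x = y
        got = np.array([wec[v] for v in nodes])
        if np.dot(got, x) < 0:
            x = -x
        assert np.allclose(got, x, atol=1e-8)

    def test_weighted_sc_matches_expm_diagonal(self):
        import scipy.linalg

        rng = np.random.default_rng(22)
        net = random_graph(rng, n_max=6, p=0.7)
        corr = corr_of(net, lambda u, v: float(rng.uniform(-1, 1)))
        wsc = weighted_centrality(net, corr, "SC")
        nodes = list(net.nodes)
        adj = np.zeros((len(nodes), len(nodes)))
        idx = {v: i for i, v in enumerate(nodes)}
        for u, v in net.edges:
            adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = corr.get(u, v)
        expected = np.diag(scipy.linalg.expm(adj))
        for v, e in zip(nodes, expected):
            assert wsc[v] == pytest.approx(e, abs=1e-10)
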