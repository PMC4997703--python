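"""The five base centrality measures, plus weighted variants.

All measures map a graph to a ``{node: score}`` dict over the full node
set.  Conventions for disconnected graphs, chosen so that isolated
proteins never outrank connected ones:

* DC — raw degree (edge count), isolated node -> 0.
* BC — unnormalized betweenness: for each node, the sum over unordered
  source-target pairs of the fraction of shortest paths through it.
  Only the induced ranking is used downstream, and per-network
  max-normalization removes scale, so the pair-count form is kept.
* CC — closeness with Wasserman–Faust component scaling, so nodes in
  small components are not inflated; isolated node -> 0.
* EC — the Perron eigenvector of the component with the largest spectral
  radius, embedded in the full node set (zeros elsewhere) and scaled to
  unit Euclidean norm.  A tie between components is broken toward the
  component containing the lexicographically smallest node.
* SC — subgraph centrality, the diagonal of exp(A) computed by symmetric
  eigendecomposition: SC(v) = sum_j phi_j(v)^2 e^{lambda_j}.  Counts
  closed walks through v with short walks weighted most; an isolated
  node scores exactly 1 (the length-0 walk).

Weighted variants (for the PCC-weighted baseline) replace the 0/1
adjacency with the signed PCC-weighted adjacency; they exist only for
DC (node strength), EC and SC, because shortest-path measures are not
defined on graphs with negative edge weights.
"""

from __future__ import annotations

from typing import Callable

import networkx as nx
import numpy as np
import scipy.linalg

from .coexpression import EdgeCorrelations, node_strengths

__all__ = [
    "degree_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "eigenvector_centrality",
    "subgraph_centrality",
    "weighted_centrality",
    "MEASURES",
]

_WEIGHTED_FORBIDDEN_MSG = (
    "BC and CC can only be applied in graphs with positive edge weights; "
    "the PCC-weighted variant exists only for DC, EC and SC"
)


def degree_centrality(net: nx.Graph) -> dict[str, float]:
    """Number of interactions of each protein."""
    return {v: float(d) for v, d in net.degree()}


def betweenness_centrality(net: nx.Graph) -> dict[str, float]:
    """Unnormalized shortest-path betweenness over unordered node pairs."""
    return {v: float(b) for v, b in nx.betweenness_centrality(net, normalized=False).items()}


def closeness_centrality(net: nx.Graph) -> dict[str, float]:
    """Closeness with Wasserman–Faust scaling for disconnected graphs."""
    return {v: float(c) for v, c in nx.closeness_centrality(net, wf_improved=True).items()}


def _component_adjacency(net: nx.Graph, nodes: list[str]) -> np.ndarray:
    return nx.to_numpy_array(net, nodelist=nodes, dtype=float)


def eigenvector_centrality(net: nx.Graph) -> dict[str, float]:
    """Nonnegative principal eigenvector of the adjacency matrix, unit norm.

    Computed exactly per connected component via symmetric
    eigendecomposition; the component with the largest spectral radius
    carries the eigenvector, every other node scores 0.
    """
    scores = {v: 0.0 for v in net.nodes}
    best: tuple[float, list[str], np.ndarray] | None = None
    for comp in nx.connected_components(net):
        nodes = sorted(comp)
        if len(nodes) == 1:
            continue  # edgeless component: spectral radius 0
        adj = _component_adjacency(net, nodes)
        vals, vecs = scipy.linalg.eigh(adj)
        lam = float(vals[-1])
        vec = vecs[:, -1]
        # Perron vector of a connected graph is strictly one-signed
        if vec.sum() < 0:
            vec = -vec
        vec = np.clip(vec, 0.0, None)
        vec /= np.linalg.norm(vec)
        if best is None or lam > best[0] + 1e-12 or (
            abs(lam - best[0]) <= 1e-12 and nodes[0] < best[1][0]
        ):
            best = (lam, nodes, vec)
    if best is not None:
        for node, x in zip(best[1], best[2]):
            scores[node] = float(x)
    return scores


def subgraph_centrality(net: nx.Graph) -> dict[str, float]:
    """Diagonal of exp(A): closed-walk counts with 1/k! length weights."""
    nodes = list(net.nodes)
    if not nodes:
        return {}
    adj = nx.to_numpy_array(net, nodelist=nodes, dtype=float)
    vals, vecs = scipy.linalg.eigh(adj)
    diag = (vecs**2) @ np.exp(vals)
    return {v: float(s) for v, s in zip(nodes, diag)}


def _weighted_adjacency(net: nx.Graph, corr: EdgeCorrelations) -> tuple[list[str], np.ndarray]:
    nodes = list(net.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)))
    for u, v in net.edges:
        w = corr.get(u, v)
        adj[idx[u], idx[v]] = w
        adj[idx[v], idx[u]] = w
    return nodes, adj


def weighted_centrality(
    net: nx.Graph, corr: EdgeCorrelations, measure: str
) -> dict[str, float]:
    """DC/EC/SC on the signed PCC-weighted adjacency.

    * ``DC`` — node strength, the signed sum of incident edge weights.
    * ``EC`` — eigenvector of the largest (algebraic) eigenvalue of the
      weighted adjacency, unit Euclidean norm, sign fixed so the entry of
      largest magnitude is positive.
    * ``SC`` — diagonal of the matrix exponential of the weighted
      adjacency.

    ``BC``/``CC`` raise: shortest paths are undefined with negative
    weights.
    """
    if measure in ("BC", "CC"):
        raise ValueError(_WEIGHTED_FORBIDDEN_MSG)
    if measure == "DC":
        return node_strengths(net, corr)
    nodes, adj = _weighted_adjacency(net, corr)
    if not nodes:
        return {}
    vals, vecs = scipy.linalg.eigh(adj)
    if measure == "EC":
        vec = vecs[:, -1]
        pivot = int(np.argmax(np.abs(vec)))
        if vec[pivot] < 0:
            vec = -vec
        return {v: float(x) for v, x in zip(nodes, vec)}
    if measure == "SC":
        diag = (vecs**2) @ np.exp(vals)
        return {v: float(s) for v, s in zip(nodes, diag)}
    raise ValueError(f"unknown measure {measure!r}; expected one of DC, EC, SC")


MEASURES: dict[str, Callable[[nx.Graph], dict[str, float]]] = {
    "DC": degree_centrality,
    "BC": betweenness_centrality,
    "CC": closeness_centrality,
    "EC": eigenvector_centrality,
    "SC": subgraph_centrality,
}
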