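"""Gene co-expression weights on protein-interaction edges.

Every edge of the interaction network is weighted by the Pearson
correlation coefficient (PCC) between the expression profiles of its two
endpoint proteins.  These weights drive the threshold-filtered network
series and the distributional analyses that motivate it: essential
proteins tend to be strongly co-expressed with some of their interaction
partners, so edges with a high co-expression weight carry more evidence
of essentiality than the bulk of the interactome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EdgeCorrelations",
    "pearson",
    "edge_correlations",
    "node_strength",
    "node_strengths",
    "ks_statistic",
    "weight_distributions",
    "ibep_fraction",
]


def _edge_key(u: str, v: str) -> tuple[str, str]:
    """Canonical (sorted) key for an undirected edge."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class EdgeCorrelations:
    """Map from undirected edge to its co-expression weight in [-1, 1].

    ``weights`` is keyed by the sorted endpoint pair; :meth:`get` accepts
    either orientation.  ``max_pcc`` / ``min_pcc`` are the extremes over
    all edges and raise on an empty map, mirroring the fact that the
    thresholding strategies are undefined without any observed PCC values.
    """

    weights: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def get(self, u: str, v: str) -> float:
        return self.weights[_edge_key(u, v)]

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return _edge_key(*edge) in self.weights

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def max_pcc(self) -> float:
        if not self.weights:
            raise ValueError("max_pcc is undefined for an empty correlation map")
        return max(self.weights.values())

    @property
    def min_pcc(self) -> float:
        if not self.weights:
            raise ValueError("min_pcc is undefined for an empty correlation map")
        return min(self.weights.values())


def pearson(x: Iterable[float], y: Iterable[float]) -> float:
    """Sample Pearson correlation between two equal-length profiles.

    Returns 0.0 when either profile has zero variance.  Proteins without
    measured expression are zero-filled upstream, which makes their
    profiles constant; scoring those edges 0 ("no co-expression
    evidence") keeps them only in low-threshold networks instead of
    propagating NaNs.  The result is clamped to [-1, 1] against rounding.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 2:
        raise ValueError("pearson requires profiles of length >= 2")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return 0.0
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def edge_correlations(net: nx.Graph, expr: pd.DataFrame) -> EdgeCorrelations:
    """Compute the PCC weight of every edge of ``net``.

    ``expr`` must cover every node of ``net`` (run
    :func:`encentra.io.attach_missing` first).  Rows are centred and
    normalised once so each edge weight is a single dot product.
    """
    missing = [v for v in net.nodes if v not in expr.index]
    if missing:
        raise KeyError(
            f"{len(missing)} network node(s) have no expression row "
            f"(e.g. {missing[0]!r}); apply attach_missing() first"
        )
    if expr.shape[1] < 2:
        raise ValueError("edge correlations need at least 2 expression samples")

    nodes = list(net.nodes)
    mat = expr.loc[nodes].to_numpy(dtype=float)
    centred = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    # zero-variance rows become zero vectors => PCC 0 by convention
    safe = np.where(norms > 0, norms, 1.0)
    unit = centred / safe[:, None]
    idx = {v: i for i, v in enumerate(nodes)}

    weights: dict[tuple[str, str], float] = {}
    for u, v in net.edges:
        w = float(np.clip(unit[idx[u]] @ unit[idx[v]], -1.0, 1.0))
        weights[_edge_key(u, v)] = w
    return EdgeCorrelations(weights)


def node_strength(net: nx.Graph, corr: EdgeCorrelations, v: str) -> float:
    """Sum of raw (signed) PCC weights over edges incident to ``v``.

    This is the node strength in the PCC-weighted network; an isolated
    node has strength 0.
    """
    if v not in net:
        raise KeyError(f"unknown node {v!r}")
    return float(sum(corr.get(v, u) for u in net.neighbors(v)))


def node_strengths(net: nx.Graph, corr: EdgeCorrelations) -> dict[str, float]:
    """Node strength of every node, in one pass over the edges."""
    out: dict[str, float] = {v: 0.0 for v in net.nodes}
    for (u, v), w in corr.weights.items():
        if u in out and v in out and net.has_edge(u, v):
            out[u] += w
            out[v] += w
    return out


def ks_statistic(a: Iterable[float], b: Iterable[float]) -> float:
    """Two-sample Kolmogorov-Smirnov statistic D = sup |ECDF_a - ECDF_b|."""
    aa = np.asarray(list(a), dtype=float)
    ba = np.asarray(list(b), dtype=float)
    if aa.size == 0 or ba.size == 0:
        raise ValueError("ks_statistic requires two non-empty samples")
    with np.errstate(divide="ignore"):  # p-value internals on size-1 samples
        return float(stats.ks_2samp(aa, ba, method="asymp").statistic)


def weight_distributions(
    net: nx.Graph,
    corr: EdgeCorrelations,
    essential: set[str],
) -> tuple[list[float], list[float]]:
    """Co-expression weight samples for essential vs nonessential proteins.

    Each edge contributes its weight once to the sample of every protein
    class found among its endpoints, so an essential-nonessential edge
    appears in both samples.
    """
    ess_sample: list[float] = []
    non_sample: list[float] = []
    for u, v in net.edges:
        w = corr.get(u, v)
        if u in essential or v in essential:
            ess_sample.append(w)
        if u not in essential or v not in essential:
            non_sample.append(w)
    return ess_sample, non_sample


def ibep_fraction(
    net: nx.Graph,
    corr: EdgeCorrelations,
    essential: set[str],
    cutoff: float,
) -> float:
    """Fraction of all edges that join two essential proteins with weight > cutoff.

    Interactions between essential proteins (IBEPs) with high
    co-expression weight are the candidate essential interactions; their
    share of the interactome is the quantity compared against the ~3 %
    of PPIs estimated to be essential.
    """
    n_edges = net.number_of_edges()
    if n_edges == 0:
        raise ValueError("ibep_fraction is undefined on an empty edge set")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    hits = sum(
        1
        for u, v in net.edges
        if u in essential and v in essential and corr.get(u, v) > cutoff
    )
    return hits / n_edges
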