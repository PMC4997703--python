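"""Evaluation machinery: top-n essential counts, ranking overlaps,
low-degree analysis and the two single-network baselines.

The headline question for any ranking method here is simple: of the top
*n* ranked proteins, how many are in the reference list of essential
proteins?  The remaining reports probe *which* proteins different
methods agree on (pairwise and joint top-n overlaps, score correlation
on the union of top-n sets) and whether a method escapes the
degree bias of plain centrality (low-degree analysis: how many of its
top picks would be invisible to the base measure because their degree in
the original network is below the base method's own top-n minimum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from statistics import mean
from typing import Mapping, Sequence

import networkx as nx

from .centrality import MEASURES, weighted_centrality
from .coexpression import EdgeCorrelations, node_strengths, pearson
from .ensemble import rank
from .io import Ranking
from .partition import filter_absolute

__all__ = [
    "OverlapCell",
    "LowDegreeReport",
    "essential_in_top",
    "top_n_curve",
    "pairwise_overlap",
    "multi_overlap",
    "low_degree_analysis",
    "union_top_correlation",
    "pcc_threshold_baseline",
    "pcc_weighted_baseline",
]


@dataclass(frozen=True)
class OverlapCell:
    """Agreement between two rankings' top-n sets."""

    n: int
    overlap: int
    essential_overlap: int

    def __post_init__(self) -> None:
        if not 0 <= self.essential_overlap <= self.overlap <= self.n:
            raise ValueError("need essential_overlap <= overlap <= n")


@dataclass(frozen=True)
class LowDegreeReport:
    """Degree statistics of an ensemble ranking vs its base measure.

    Degrees and node strengths always refer to the ORIGINAL network.
    ``low_degree_count`` is the number of ensemble top-n proteins whose
    original-network degree is below the minimum degree found in the base
    measure's top n; such proteins are by construction absent from the
    base method's top-n set.
    """

    n: int
    ens_avg_degree: float
    ens_min_degree: int
    base_avg_degree: float
    base_min_degree: int
    low_degree_count: int
    low_degree_essential_count: int
    ens_avg_strength: float
    base_avg_strength: float


def _check_boundary_tie(ranking: Ranking, n: int) -> None:
    if 0 < n < len(ranking.entries):
        if ranking.entries[n - 1][1] == ranking.entries[n][1]:
            warnings.warn(
                f"score tie spans the top-{n} boundary; membership decided "
                "by the deterministic tie order",
                stacklevel=3,
            )


def essential_in_top(ranking: Ranking, essential: set[str], n: int) -> int:
    """Number of true essential proteins among the top n ranked."""
    if n < 1:
        raise ValueError("n must be >= 1")
    _check_boundary_tie(ranking, n)
    return sum(1 for p in ranking.top(n) if p in essential)


def top_n_curve(
    ranking: Ranking, essential: set[str], ns: Sequence[int]
) -> dict[int, int]:
    """essential_in_top evaluated at each n (the top-n performance curve)."""
    return {n: essential_in_top(ranking, essential, n) for n in ns}


def pairwise_overlap(
    rank_a: Ranking, rank_b: Ranking, essential: set[str], n: int
) -> OverlapCell:
    """Common proteins (and common essentials) among two top-n sets."""
    _check_boundary_tie(rank_a, n)
    _check_boundary_tie(rank_b, n)
    common = set(rank_a.top(n)) & set(rank_b.top(n))
    return OverlapCell(n=n, overlap=len(common), essential_overlap=len(common & essential))


def multi_overlap(
    rankings: Sequence[Ranking], essential: set[str], n: int
) -> tuple[int, int]:
    """Joint top-n overlap across all rankings, and its essential subset."""
    if len(rankings) < 2:
        raise ValueError("multi_overlap needs at least 2 rankings")
    common = set(rankings[0].top(n))
    for r in rankings[1:]:
        common &= set(r.top(n))
    return len(common), len(common & essential)


def low_degree_analysis(
    ens_rank: Ranking,
    base_rank: Ranking,
    net: nx.Graph,
    corr: EdgeCorrelations,
    essential: set[str],
    n: int,
) -> LowDegreeReport:
    """Degree/strength profile of the ensemble's top n against the base's."""
    ens_top = ens_rank.top(n)
    base_top = base_rank.top(n)
    strengths = node_strengths(net, corr)

    ens_deg = [net.degree(p) for p in ens_top]
    base_deg = [net.degree(p) for p in base_top]
    base_min = min(base_deg)
    low = [p for p in ens_top if net.degree(p) < base_min]
    # by definition a low-degree pick cannot be in the base top-n set
    assert not set(low) & set(base_top)
    return LowDegreeReport(
        n=n,
        ens_avg_degree=mean(ens_deg),
        ens_min_degree=min(ens_deg),
        base_avg_degree=mean(base_deg),
        base_min_degree=base_min,
        low_degree_count=len(low),
        low_degree_essential_count=sum(1 for p in low if p in essential),
        ens_avg_strength=mean(strengths[p] for p in ens_top),
        base_avg_strength=mean(strengths[p] for p in base_top),
    )


def union_top_correlation(
    scores_a: Mapping[str, float],
    scores_b: Mapping[str, float],
    rank_a: Ranking,
    rank_b: Ranking,
    n: int,
) -> float:
    """Pearson correlation of two methods' scores over the union of their top-n sets."""
    union = sorted(set(rank_a.top(n)) | set(rank_b.top(n)))
    if len(union) < 2:
        raise ValueError("union of top-n sets has fewer than 2 proteins")
    return pearson([scores_a[p] for p in union], [scores_b[p] for p in union])


def pcc_threshold_baseline(
    net: nx.Graph,
    corr: EdgeCorrelations,
    measure: str,
    thr: float = 0.75,
) -> Ranking:
    """Single-network baseline: the measure on the |PCC| >= thr filtered network.

    The default cutoff 0.75 is where the co-expression weight
    distributions of essential and nonessential proteins visibly
    separate.  Zero-degree proteins score 0 (and tie at the bottom).
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {sorted(MEASURES)}")
    filtered = filter_absolute(net, corr, thr)
    scores = MEASURES[measure](filtered)
    degrees = dict(filtered.degree())
    masked = {p: (s if degrees.get(p, 0) > 0 else 0.0) for p, s in scores.items()}
    return rank(masked)


def pcc_weighted_baseline(
    net: nx.Graph, corr: EdgeCorrelations, measure: str
) -> Ranking:
    """Single-network baseline: DC/EC/SC on the PCC-weighted original network."""
    return rank(weighted_centrality(net, corr, measure))
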