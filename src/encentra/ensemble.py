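"""Grading, weighted-voting integration and ranking — the framework core.

Given the threshold-filtered network series, each protein is scored with
one base centrality measure on every member network (*grading*).  Scores
from one member are made comparable across members by dividing by their
maximum, after zero-degree proteins in that member are masked to 0.  The
``m`` normalized scores of protein *j* are then combined by weighted
voting into a final score

    fs(j) = sum_i s(j, i) * w_i,

with a non-decreasing weight vector ``w`` that gives the sparser,
high-co-expression networks the larger say while keeping weight 1 on the
original network so no information from it is discarded (*integrating*).
Proteins are ranked by ``fs`` in descending order (*ranking*).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .centrality import MEASURES
from .coexpression import edge_correlations
from .io import Ranking, attach_missing
from .partition import NetworkSeries, ThresholdSchedule, build_series, default_schedule

__all__ = [
    "ScoreMatrix",
    "grade",
    "default_weights",
    "named_weights",
    "validate_weights",
    "integrate",
    "rank",
    "run_ensemble",
]


@dataclass(frozen=True)
class ScoreMatrix:
    """Protein-by-network matrix of max-normalized centrality scores s(j, i).

    Every column is either all zero (an edgeless member network) or has
    maximum exactly 1.
    """

    proteins: tuple[str, ...]
    thresholds: tuple[float, ...]
    values: np.ndarray  # shape (len(proteins), len(thresholds))

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.proteins), len(self.thresholds)):
            raise ValueError("score matrix shape does not match protein/threshold labels")


def grade(series: NetworkSeries, measure: str) -> ScoreMatrix:
    """Score every protein on every member network with one measure.

    Per member: compute the measure, set the score of every zero-degree
    protein to 0 (a protein with no remaining interactions carries no
    evidence — this also flattens the SC floor of 1 that isolated nodes
    would otherwise keep), then divide the column by its maximum.
    Columns that are entirely zero are left as zeros.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {sorted(MEASURES)}")
    fn = MEASURES[measure]
    proteins = tuple(series.base.nodes)
    cols = []
    for _, member in series.members:
        scores = fn(member)
        degrees = dict(member.degree())
        col = np.array(
            [scores[p] if degrees.get(p, 0) > 0 else 0.0 for p in proteins], dtype=float
        )
        peak = col.max(initial=0.0)
        if peak > 0:
            col = col / peak
        cols.append(col)
    values = np.column_stack(cols) if cols else np.zeros((len(proteins), 0))
    return ScoreMatrix(proteins=proteins, thresholds=series.thresholds, values=values)


def _fibonacci_like(n: int) -> list[float]:
    w = [1.0, 2.0]
    while len(w) < n:
        w.append(w[-1] + w[-2])
    return w[:n]


def default_weights(strategy: str) -> tuple[float, ...]:
    """The default voting weights matched to :func:`default_schedule`.

    Absolute (m=15): the dominant weighting 1, 2, 3, 5, 8, ..., 987 —
    each weight the sum of its two predecessors, so the high-threshold
    members dominate the vote.  Uniform (m=19): weight 1 for the eight
    negative thresholds (filtering there barely changes the network),
    then the same doubling ramp 2, 3, 5, ..., 233.
    """
    if strategy == "absolute":
        return tuple(_fibonacci_like(15))
    if strategy == "uniform":
        return tuple([1.0] * 8 + _fibonacci_like(12)[1:])
    raise ValueError(f"unknown strategy {strategy!r}; expected 'absolute' or 'uniform'")


def named_weights(name: str) -> tuple[float, ...]:
    """The four named 15-element weight vectors for the absolute schedule.

    * ``w1`` — all ones (unweighted voting baseline);
    * ``w2`` — 1..15, gradual advance weighting;
    * ``w3`` — eight 1s then 8, 9, 10, 11, 12, 13, 15, prior-guided
      advance weighting (flat until the threshold-0.7 regime where all
      measures start improving);
    * ``w4`` — 1, 2, 3, 5, 8, ..., 987, dominant weighting.
    """
    table: dict[str, list[float]] = {
        "w1": [1.0] * 15,
        "w2": [float(i) for i in range(1, 16)],
        "w3": [1.0] * 8 + [8.0, 9.0, 10.0, 11.0, 12.0, 13.0, 15.0],
        "w4": _fibonacci_like(15),
    }
    if name not in table:
        raise ValueError(f"unknown weight vector {name!r}; expected one of {sorted(table)}")
    return tuple(table[name])


def validate_weights(weights: Sequence[float]) -> tuple[float, ...]:
    """Check a voting weight vector: positive, ideally non-decreasing.

    A decreasing step only warns: plateaus and custom emphases are
    legitimate, but decreasing weights contradict the premise that
    higher-threshold networks carry more evidence.
    """
    w = tuple(float(x) for x in weights)
    if any(x <= 0 for x in w):
        raise ValueError("voting weights must be positive")
    if any(a > b for a, b in zip(w, w[1:])):
        warnings.warn("voting weights are not non-decreasing", stacklevel=2)
    return w


def integrate(sm: ScoreMatrix, weights: Sequence[float]) -> dict[str, float]:
    """Final score fs(j) = sum_i s(j, i) * w_i for every protein."""
    w = np.asarray(list(weights), dtype=float)
    if w.size != sm.values.shape[1]:
        raise ValueError(
            f"weight vector length {w.size} does not match {sm.values.shape[1]} networks"
        )
    fs = sm.values @ w
    return {p: float(s) for p, s in zip(sm.proteins, fs)}


def rank(
    fs: Mapping[str, float],
    *,
    tie_break: str = "id",
    seed: int | None = None,
) -> Ranking:
    """Order proteins by final score, descending.

    Exact ties are broken by ascending protein identifier
    (``tie_break="id"``, deterministic) or, with ``tie_break="random"``,
    by a seeded shuffle within each tied block.
    """
    if tie_break == "id":
        entries = sorted(fs.items(), key=lambda kv: (-kv[1], kv[0]))
    elif tie_break == "random":
        rng = np.random.default_rng(seed)
        jitter = {p: rng.random() for p in fs}
        entries = sorted(fs.items(), key=lambda kv: (-kv[1], jitter[kv[0]]))
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}; expected 'id' or 'random'")
    return Ranking(tuple(entries))


def run_ensemble(
    net: nx.Graph,
    expr: pd.DataFrame,
    measure: str,
    strategy: str = "absolute",
    schedule: ThresholdSchedule | Sequence[float] | None = None,
    weights: Sequence[float] | None = None,
    *,
    tie_break: str = "id",
    seed: int | None = None,
) -> Ranking:
    """The full four-step pipeline on one network + expression matrix.

    Steps: zero-fill missing expression, weight every edge by PCC, build
    the threshold-filtered series, grade with ``measure``, integrate with
    ``weights`` (default: the strategy's dominant weighting) and rank.
    """
    if schedule is None:
        sched = default_schedule(strategy)
    elif isinstance(schedule, ThresholdSchedule):
        sched = schedule
    else:
        sched = ThresholdSchedule(strategy, tuple(float(t) for t in schedule))
    w = validate_weights(default_weights(strategy) if weights is None else weights)
    if len(w) != len(sched):
        raise ValueError(f"{len(w)} weights for {len(sched)} thresholds")

    expr_full = attach_missing(net, expr)
    corr = edge_correlations(net, expr_full)
    series = build_series(net, corr, sched)
    sm = grade(series, measure)
    fs = integrate(sm, w)
    return rank(fs, tie_break=tie_break, seed=seed)
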