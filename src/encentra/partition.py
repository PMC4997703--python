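"""Threshold schedules and the correlation-filtered network series.

From the original network, ``m`` progressively sparser networks are
generated by deleting edges whose co-expression weight falls below an
increasing sequence of thresholds.  Two strategies exist:

* **absolute** — keep edge ``e`` iff ``|PCC(e)| >= thr`` (strong negative
  co-expression also counts as evidence);
* **uniform** — keep edge ``e`` iff ``PCC(e) >= thr`` (signed comparison,
  so thresholds may be negative).

Nodes are never removed: every member of the series shares the node set
of the original network, only degrees change.  Because thresholds are
strictly increasing and retention uses ``>=``, member edge sets are
nested (non-increasing) and the threshold-0 member of the absolute
schedule is exactly the original network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .coexpression import EdgeCorrelations

__all__ = [
    "ThresholdSchedule",
    "NetworkSeries",
    "default_schedule",
    "filter_absolute",
    "filter_uniform",
    "build_series",
]

STRATEGIES = ("absolute", "uniform")


@dataclass(frozen=True)
class ThresholdSchedule:
    """A strictly increasing sequence of PCC thresholds for one strategy."""

    strategy: str
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}")
        if any(a >= b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if self.strategy == "absolute" and any(t < 0 for t in self.thresholds):
            raise ValueError("absolute thresholds must be non-negative")

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class NetworkSeries:
    """The original network plus its ``m`` threshold-filtered members."""

    base: nx.Graph
    members: tuple[tuple[float, nx.Graph], ...]

    @property
    def thresholds(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.members)

    def __len__(self) -> int:
        return len(self.members)


def default_schedule(strategy: str) -> ThresholdSchedule:
    """The default threshold lists: m=15 (absolute) and m=19 (uniform).

    Absolute: 0, 0.1, ..., 0.8 then 0.9, 0.91, ..., 0.95 — coarse steps
    through the bulk of the PCC distribution and dense sampling of the
    highly co-expressed tail.  Uniform: -0.7, -0.6, ..., 0.8 then 0.9,
    0.91, 0.92.
    """
    if strategy == "absolute":
        thr = [round(0.1 * i, 2) for i in range(9)] + [round(0.9 + 0.01 * i, 2) for i in range(6)]
    elif strategy == "uniform":
        thr = [round(-0.7 + 0.1 * i, 2) for i in range(16)] + [0.9, 0.91, 0.92]
    else:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    return ThresholdSchedule(strategy, tuple(thr))


def _filtered(net: nx.Graph, keep_edges) -> nx.Graph:
    out = nx.Graph()
    out.add_nodes_from(net.nodes)
    out.add_edges_from(keep_edges)
    return out


def filter_absolute(net: nx.Graph, corr: EdgeCorrelations, thr: float) -> nx.Graph:
    """Keep edges with ``|PCC| >= thr``; node set unchanged."""
    if thr < 0:
        raise ValueError("absolute threshold must be non-negative")
    return _filtered(net, ((u, v) for u, v in net.edges if abs(corr.get(u, v)) >= thr))


def filter_uniform(net: nx.Graph, corr: EdgeCorrelations, thr: float) -> nx.Graph:
    """Keep edges with signed ``PCC >= thr``; node set unchanged."""
    return _filtered(net, ((u, v) for u, v in net.edges if corr.get(u, v) >= thr))


_FILTERS = {"absolute": filter_absolute, "uniform": filter_uniform}


def build_series(
    net: nx.Graph, corr: EdgeCorrelations, schedule: ThresholdSchedule
) -> NetworkSeries:
    """Apply the schedule's filter at every threshold, in order."""
    filt = _FILTERS[schedule.strategy]
    members = tuple((thr, filt(net, corr, thr)) for thr in schedule.thresholds)
    return NetworkSeries(base=net, members=members)
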