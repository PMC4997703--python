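"""Readers and writers for the three plain-text input formats.

* PPI network: tab/whitespace-delimited edge list, two identifier columns,
  ``#`` comments, extra columns ignored (so database exports reduced to
  two columns still load).
* Expression matrix: TSV with a header row of sample labels, then one row
  per protein (identifier followed by numeric values).
* Essential-protein reference: one identifier per line.

Identifiers are compared case-sensitively after stripping surrounding
whitespace; yeast ORF names are case-sensitive by convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .coexpression import EdgeCorrelations, node_strengths

__all__ = [
    "Ranking",
    "read_network",
    "read_expression",
    "attach_missing",
    "read_essential_set",
    "write_ranking",
    "read_ranking",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Ranking:
    """Proteins ordered by final score, descending.

    ``entries`` is a list of ``(protein_id, score)`` pairs with
    non-increasing scores; exact ties are broken by ascending identifier
    unless a seeded random tie-break was requested at construction.
    """

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("ranking scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.entries)

    def top(self, n: int) -> list[str]:
        """Identifiers of the ``n`` highest-ranked proteins."""
        if n > len(self.entries):
            raise ValueError(f"requested top {n} of a {len(self.entries)}-protein ranking")
        return [p for p, _ in self.entries[:n]]

    def ids(self) -> list[str]:
        return [p for p, _ in self.entries]

    def scores(self) -> dict[str, float]:
        return dict(self.entries)


def read_network(path: str | Path) -> nx.Graph:
    """Read an undirected PPI edge list into a simple graph.

    Self-interactions are dropped and duplicate interactions (in either
    orientation) are collapsed; the counts of both are logged.  Lines
    starting with ``#`` and blank lines are skipped, and columns beyond
    the first two are ignored.
    """
    path = Path(path)
    net = nx.Graph()
    n_self = 0
    n_dup = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns, got {len(cols)}")
            u, v = cols[0].strip(), cols[1].strip()
            if u == v:
                n_self += 1
                net.add_node(u)
                continue
            if net.has_edge(u, v):
                n_dup += 1
                continue
            net.add_edge(u, v)
    logger.info(
        "read %s: %d proteins, %d interactions (%d self-interactions and "
        "%d repeated interactions removed)",
        path, net.number_of_nodes(), net.number_of_edges(), n_self, n_dup,
    )
    return net


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample expression table.

    The first row holds sample labels; every following row is a protein
    identifier and one numeric value per sample.  Rows with non-numeric
    or missing cells are rejected with their line number, and duplicate
    protein identifiers are an error.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame.index = frame.index.astype(str).str.strip()
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate protein id {dup!r}")
    values = frame.apply(pd.to_numeric, errors="coerce")
    bad = values.isna().any(axis=1)
    if bad.any():
        # +2: one for the header row, one for 1-based numbering
        lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"{path}:{lineno}: non-numeric or missing value in row {bad.idxmax()!r}")
    values.columns = [str(c).strip() for c in frame.columns]
    return values.astype(float)


def attach_missing(net: nx.Graph, expr: pd.DataFrame) -> pd.DataFrame:
    """Extend ``expr`` with an all-zero row for every network protein it lacks.

    Proteins with no measured expression are given constant-zero
    profiles; downstream their edges get PCC 0.  Existing rows (including
    rows for proteins outside the network) are kept unchanged.
    """
    if expr.shape[1] == 0:
        raise ValueError("expression matrix has no samples")
    missing = [v for v in net.nodes if v not in expr.index]
    if not missing:
        return expr
    zeros = pd.DataFrame(
        np.zeros((len(missing), expr.shape[1])), index=missing, columns=expr.columns
    )
    return pd.concat([expr, zeros])


def read_essential_set(path: str | Path) -> set[str]:
    """Read a one-identifier-per-line essential-protein reference list."""
    path = Path(path)
    out: set[str] = set()
    with path.open() as fh:
        for raw in fh:
            pid = raw.strip()
            if pid:
                out.add(pid)
    return out


def write_ranking(
    rank: Ranking,
    net: nx.Graph,
    essential: set[str],
    corr: EdgeCorrelations,
    path: str | Path,
) -> None:
    """Write a ranking as TSV: rank, protein, score, degree, node_strength, is_essential.

    Scores and node strengths are printed with full float precision
    (shortest round-trip representation) so a re-read reproduces them
    exactly.
    """
    unknown = [p for p, _ in rank.entries if p not in net]
    if unknown:
        raise ValueError(f"ranked protein {unknown[0]!r} is not a network node")
    strengths = node_strengths(net, corr)
    with Path(path).open("w") as fh:
        fh.write("rank\tprotein\tscore\tdegree\tnode_strength\tis_essential\n")
        for i, (pid, score) in enumerate(rank.entries, start=1):
            fh.write(
                f"{i}\t{pid}\t{score!r}\t{net.degree(pid)}\t"
                f"{strengths[pid]!r}\t{int(pid in essential)}\n"
            )


def read_ranking(path: str | Path) -> Ranking:
    """Re-read a ranking TSV written by :func:`write_ranking`."""
    frame = pd.read_csv(path, sep="\t", dtype={"protein": str})
    entries = tuple(zip(frame["protein"].tolist(), frame["score"].astype(float).tolist()))
    return Ranking(entries)
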