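"""Directed regulatory networks as edge sets with optional weight and lag."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd


@dataclass(frozen=True, order=True)
class Edge:
    """A directed regulator -> target edge with optional weight and lag."""

    regulator: str
    target: str
    weight: float | None = None
    lag: int | None = None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.regulator, self.target)


class RegulatoryNetwork:
    """A set of directed edges over a fixed gene universe.

    Duplicate (regulator, target) pairs are rejected; endpoints must belong
    to ``gene_ids``.
    """

    def __init__(self, gene_ids, edges=()):
        self.gene_ids: tuple[str, ...] = tuple(gene_ids)
        gene_set = set(self.gene_ids)
        if len(gene_set) != len(self.gene_ids):
            raise ValueError("gene_ids must be distinct")
        self._edges: dict[tuple[str, str], Edge] = {}
        for e in edges:
            if not isinstance(e, Edge):
                e = Edge(*e)
            if e.regulator not in gene_set or e.target not in gene_set:
                raise ValueError(f"edge endpoint not in gene_ids: {e}")
            if e.pair in self._edges:
                raise ValueError(f"duplicate edge {e.pair}")
            self._edges[e.pair] = e

    @property
    def edges(self) -> frozenset[Edge]:
        return frozenset(self._edges.values())

    @property
    def pairs(self) -> frozenset[tuple[str, str]]:
        """Unweighted (regulator, target) pairs — the unit of scoring."""
        return frozenset(self._edges)

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self._edges

    def __getitem__(self, pair) -> Edge:
        return self._edges[tuple(pair)]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RegulatoryNetwork)
            and self.gene_ids == other.gene_ids
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return f"RegulatoryNetwork({len(self.gene_ids)} genes, {len(self)} edges)"

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.gene_ids)
        for e in self._edges.values():
            g.add_edge(e.regulator, e.target, weight=e.weight, lag=e.lag)
        return g

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "regulator": e.regulator,
                "target": e.target,
                "weight": e.weight if e.weight is not None else math.nan,
                "lag": e.lag if e.lag is not None else -1,
            }
            for e in sorted(self._edges.values())
        ]
        return pd.DataFrame(rows, columns=["regulator", "target", "weight", "lag"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, gene_ids=None) -> "RegulatoryNetwork":
        """Read an edge-list TSV (regulator, target[, weight[, lag]]).

        When ``gene_ids`` is omitted the universe is the set of endpoint
        names, sorted.
        """
        df = pd.read_csv(path, sep="\t")
        edges = []
        for row in df.itertuples(index=False):
            weight = getattr(row, "weight", None)
            if weight is not None and pd.isna(weight):
                weight = None
            lag = getattr(row, "lag", None)
            if lag is not None:
                lag = int(lag)
                if lag < 0:
                    lag = None
            edges.append(Edge(str(row.regulator), str(row.target), weight, lag))
        if gene_ids is None:
            gene_ids = sorted({e.regulator for e in edges} | {e.target for e in edges})
        return cls(gene_ids, edges)
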