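"""Two-stage hub-gene selection from a centrality table.

Stage 1 (candidates): keep the top 20% of nodes on each of degree,
closeness and betweenness, and intersect the three sets.
Stage 2 (hubs): take the top k=20 nodes per centrality and intersect.

Ranking is by descending centrality value with lexicographic identifier
as the tie-break, and the cut takes exactly ceil(fraction*n) (or k)
entries, so results are fully reproducible. A ``ties="all"`` mode
instead extends the cut to include every node tied with the last one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .centrality import CENTRALITY_NAMES
from .identifiers import GeneSet

__all__ = ["HubSelectionResult", "rank_nodes", "top_fraction", "top_k",
           "select_candidates", "select_hubs", "select"]


def rank_nodes(table: pd.DataFrame, centrality: str) -> list[str]:
    """Node ids sorted by descending centrality value, ties by id."""
    if centrality not in table.columns:
        raise ValueError(
            f"unknown centrality {centrality!r}; expected one of {list(table.columns)}"
        )
    col = table[centrality]
    return sorted(table.index, key=lambda v: (-col.at[v], v))


def _cut(table: pd.DataFrame, centrality: str, m: int, ties: str) -> list[str]:
    ranked = rank_nodes(table, centrality)
    if ties == "exact" or m == 0 or m >= len(ranked):
        return ranked[:m]
    if ties != "all":
        raise ValueError(f"ties must be 'exact' or 'all', got {ties!r}")
    col = table[centrality]
    boundary = col.at[ranked[m - 1]]
    while m < len(ranked) and col.at[ranked[m]] == boundary:
        m += 1
    return ranked[:m]


def top_fraction(
    table: pd.DataFrame, centrality: str, fraction: float, ties: str = "exact"
) -> list[str]:
    """The ceil(fraction*n) highest-ranked nodes by one centrality."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    return _cut(table, centrality, math.ceil(fraction * len(table)), ties)


def top_k(
    table: pd.DataFrame, centrality: str, k: int, ties: str = "exact"
) -> list[str]:
    """The k highest-ranked nodes by one centrality."""
    if not 1 <= k <= len(table):
        raise ValueError(f"k must be in [1, {len(table)}]")
    return _cut(table, centrality, k, ties)


def _combine(lists: dict[str, list[str]], combine: str) -> frozenset[str]:
    sets = [set(v) for v in lists.values()]
    if combine == "intersection":
        return frozenset(set.intersection(*sets))
    if combine == "union":
        return frozenset(set.union(*sets))
    raise ValueError(f"combine must be 'intersection' or 'union', got {combine!r}")


def select_candidates(
    table: pd.DataFrame,
    fraction: float = 0.20,
    combine: str = "intersection",
    ties: str = "exact",
) -> GeneSet:
    """Hub candidates: nodes in the top ``fraction`` of all three centralities."""
    lists = {c: top_fraction(table, c, fraction, ties) for c in CENTRALITY_NAMES}
    return GeneSet.from_strings("hub_candidates", _combine(lists, combine))


def select_hubs(table: pd.DataFrame, k: int = 20, ties: str = "exact") -> GeneSet:
    """Hub genes: the intersection of the three per-centrality top-k lists."""
    lists = {c: top_k(table, c, k, ties) for c in CENTRALITY_NAMES}
    return GeneSet.from_strings("hub_genes", _combine(lists, "intersection"))


@dataclass
class HubSelectionResult:
    """Candidates, hubs and the per-centrality ranked lists behind them."""

    candidates: GeneSet
    hubs: GeneSet
    top_lists: dict[str, list[str]] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters,
            "candidates": sorted(self.candidates.keys()),
            "hubs": sorted(self.hubs.keys()),
            "top_lists": self.top_lists,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def select(
    table: pd.DataFrame,
    fraction: float = 0.20,
    k: int = 20,
    combine: str = "intersection",
    ties: str = "exact",
) -> HubSelectionResult:
    """Run both stages and bundle the result."""
    k = min(k, len(table)) if len(table) else k
    return HubSelectionResult(
        candidates=select_candidates(table, fraction, combine, ties),
        hubs=select_hubs(table, k, ties),
        top_lists={c: top_k(table, c, k, ties) for c in CENTRALITY_NAMES},
        parameters={"fraction": fraction, "k": k, "combine": combine, "ties": ties},
    )
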