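"""Degree, closeness and betweenness centrality with Cytoscape-style conventions.

The hub-selection stage ranks nodes on exactly three centralities, using
the conventions of Cytoscape's NetworkAnalyzer:

* degree — raw neighbour count (an integer, not divided by n-1);
* closeness — within each connected component, (m-1) / sum of shortest
  path distances, i.e. the reciprocal of the mean distance to the other
  m-1 nodes of the component; isolated nodes score 0;
* betweenness — Brandes' algorithm with endpoints excluded, normalised by
  2/((m-1)(m-2)) where m is the node's component size (components with
  m < 3 score 0). Whole-graph normalisation and unnormalised values are
  available by flag.

Node iteration order is fixed (sorted identifiers) so floating-point
accumulation — and hence every downstream ranking — is reproducible.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .graph_core import PPINetwork

__all__ = [
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "compute_centralities",
    "write_centrality_table",
    "read_centrality_table",
]

CENTRALITY_NAMES = ("degree", "closeness", "betweenness")


def _ordered_graph(net: PPINetwork) -> nx.Graph:
    """Copy with nodes and edges inserted in sorted order (determinism)."""
    g = nx.Graph()
    g.add_nodes_from(sorted(net.graph.nodes))
    for a, b, c in net.edges():
        g.add_edge(a, b, confidence=c)
    return g


def degree_centrality(net: PPINetwork) -> dict[str, int]:
    """Raw degree: number of distinct neighbours of each node."""
    g = _ordered_graph(net)
    return {v: int(d) for v, d in g.degree()}


def closeness_centrality(net: PPINetwork) -> dict[str, float]:
    """Per-component closeness (reciprocal mean shortest-path distance)."""
    g = _ordered_graph(net)
    # wf_improved=False is exactly the within-component convention:
    # (m-1)/sum(dist) with no rescaling by the whole-graph size.
    return dict(nx.closeness_centrality(g, wf_improved=False))


def betweenness_centrality(
    net: PPINetwork, normalized: bool = True, per_component: bool = True
) -> dict[str, float]:
    """Shortest-path betweenness, endpoints excluded.

    ``normalized`` divides by the number of node pairs that could route
    through a vertex; with ``per_component`` that count uses the vertex's
    component size m — 2/((m-1)(m-2)) — otherwise the whole-graph size.
    """
    g = _ordered_graph(net)
    raw = nx.betweenness_centrality(g, normalized=False)
    if not normalized:
        return raw
    out: dict[str, float] = {}
    if per_component:
        for comp in nx.connected_components(g):
            m = len(comp)
            scale = 2.0 / ((m - 1) * (m - 2)) if m >= 3 else 0.0
            for v in comp:
                out[v] = raw[v] * scale
    else:
        n = g.number_of_nodes()
        scale = 2.0 / ((n - 1) * (n - 2)) if n >= 3 else 0.0
        out = {v: raw[v] * scale for v in raw}
    return {v: out[v] for v in sorted(out)}


def compute_centralities(
    net: PPINetwork, betweenness_per_component: bool = True
) -> pd.DataFrame:
    """All three centralities as a DataFrame indexed by node id.

    Columns: ``degree`` (int), ``closeness``, ``betweenness``.
    """
    deg = degree_centrality(net)
    clo = closeness_centrality(net)
    btw = betweenness_centrality(net, per_component=betweenness_per_component)
    idx = sorted(net.graph.nodes)
    return pd.DataFrame(
        {
            "degree": pd.Series({v: deg[v] for v in idx}, dtype=int),
            "closeness": pd.Series({v: clo[v] for v in idx}),
            "betweenness": pd.Series({v: btw[v] for v in idx}),
        }
    ).loc[idx]


def write_centrality_table(table: pd.DataFrame, path: str | Path) -> None:
    """TSV (id, degree, closeness, betweenness) sorted by degree desc, id asc."""
    order = sorted(table.index, key=lambda v: (-table.at[v, "degree"], v))
    # %.17g round-trips doubles exactly through the text file
    table.loc[order].to_csv(path, sep="\t", index_label="id", float_format="%.17g")


def read_centrality_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="id", float_precision="round_trip")
    df["degree"] = df["degree"].astype(int)
    return df
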