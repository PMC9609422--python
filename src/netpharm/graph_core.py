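"""Parsing, cleaning, filtering and summarising protein interaction networks.

A :class:`PPINetwork` is a simple undirected graph — no self-loops, no
parallel edges — whose edges carry an interaction confidence in [0, 1]
(STRING-style combined scores rescaled to the unit interval). All
downstream analyses (centrality ranking, MCODE module detection) consume
this container, so the cleaning guarantees are enforced here once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx

__all__ = [
    "PPINetwork",
    "NetworkSummary",
    "read_edge_list",
    "write_edge_list",
    "filter_by_confidence",
    "network_summary",
]


@dataclass
class PPINetwork:
    """Simple undirected interaction network with per-edge confidence.

    Nodes are identifier strings; edge data holds ``confidence`` in [0, 1].
    ``metadata`` is free-form provenance (source file, filter threshold,
    parse report).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    metadata: dict = field(default_factory=dict)

    # -- construction -------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        metadata: dict | None = None,
    ) -> "PPINetwork":
        """Build from ``(a, b, confidence)`` triples, cleaning as we go.

        Self-loops are dropped; duplicate edges (in either orientation)
        are collapsed keeping the maximum confidence.
        """
        g = nx.Graph()
        dropped_self_loops = 0
        collapsed = 0
        for a, b, c in edges:
            c = float(c)
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"confidence {c} outside [0, 1] for edge ({a}, {b})")
            if a == b:
                dropped_self_loops += 1
                continue
            if g.has_edge(a, b):
                collapsed += 1
                if c > g.edges[a, b]["confidence"]:
                    g.edges[a, b]["confidence"] = c
            else:
                g.add_edge(a, b, confidence=c)
        meta = dict(metadata or {})
        meta.setdefault("parse_report", {})
        meta["parse_report"].update(
            {"self_loops_dropped": dropped_self_loops, "duplicates_collapsed": collapsed}
        )
        return cls(g, meta)

    # -- basic views --------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        """Canonical edge list: endpoints sorted within and across edges."""
        rows = [
            (min(a, b), max(a, b), d["confidence"])
            for a, b, d in self.graph.edges(data=True)
        ]
        rows.sort()
        return rows

    def density(self) -> float:
        v = self.n_nodes
        if v < 2:
            return 0.0
        return 2.0 * self.n_edges / (v * (v - 1))

    def copy(self) -> "PPINetwork":
        return PPINetwork(self.graph.copy(), dict(self.metadata))

    def validate(self) -> None:
        """Assert the simple-graph invariant; raises on violation."""
        if any(a == b for a, b in self.graph.edges):
            raise AssertionError("self-loop present")
        for a, b, d in self.graph.edges(data=True):
            c = d.get("confidence")
            if c is None or not 0.0 <= c <= 1.0:
                raise AssertionError(f"bad confidence on edge ({a}, {b}): {c}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return (
            set(self.graph.nodes) == set(other.graph.nodes)
            and self.edges() == other.edges()
        )


class NetworkSummary(NamedTuple):
    n_nodes: int
    n_edges: int
    density: float
    n_components: int
    largest_component_size: int


def _parse_tsv(text: str, path: str) -> list[tuple[str, str, float | None]]:
    rows: list[tuple[str, str, float | None]] = []
    first_data_line = True
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected >=2 columns, got {len(fields)}")
        conf: float | None = None
        if len(fields) >= 3:
            try:
                conf = float(fields[2])
            except ValueError:
                if first_data_line:
                    # header row: third field non-numeric on line 1
                    first_data_line = False
                    continue
                raise ValueError(
                    f"{path}:{lineno}: confidence {fields[2]!r} is not a number"
                ) from None
            if not 0.0 <= conf <= 1.0:
                raise ValueError(f"{path}:{lineno}: confidence {conf} outside [0, 1]")
        first_data_line = False
        rows.append((fields[0], fields[1], conf))
    return rows


def _parse_sif(text: str, path: str) -> list[tuple[str, str, float | None]]:
    # "nodeA <relation> nodeB [nodeC ...]": one source, a relation token,
    # one or more targets; the relation is discarded.
    rows: list[tuple[str, str, float | None]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) == 1:
            raise ValueError(f"{path}:{lineno}: lone node without interaction")
        if len(fields) == 2:
            raise ValueError(
                f"{path}:{lineno}: SIF row needs 'source relation target'"
            )
        src = fields[0]
        for tgt in fields[2:]:
            rows.append((src, tgt, None))
    return rows


def read_edge_list(
    path: str | Path,
    format: str | None = None,
    default_confidence: float = 1.0,
) -> PPINetwork:
    """Read a TSV or SIF edge list into a cleaned :class:`PPINetwork`.

    TSV rows are ``a<TAB>b[<TAB>confidence]``; a header line is detected by
    a non-numeric third field on the first data line, and ``#`` lines are
    comments. SIF rows are ``a relation b [c ...]`` with the relation
    ignored and every edge given ``default_confidence``. Duplicate edges
    collapse to the maximum confidence; self-loops are dropped; a parse
    report lands in ``metadata``.
    """
    path = Path(path)
    if format is None:
        format = "sif" if path.suffix.lower() == ".sif" else "tsv"
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format: {format!r}")
    if not 0.0 <= default_confidence <= 1.0:
        raise ValueError("default_confidence must be in [0, 1]")
    text = path.read_text()
    rows = _parse_tsv(text, str(path)) if format == "tsv" else _parse_sif(text, str(path))
    if not rows:
        raise ValueError(f"{path}: no interaction rows found")
    triples = [
        (a, b, c if c is not None else default_confidence) for a, b, c in rows
    ]
    net = PPINetwork.from_edges(triples)
    net.metadata["source"] = str(path)
    net.metadata["format"] = format
    net.metadata["parse_report"]["rows_read"] = len(rows)
    return net


def write_edge_list(net: PPINetwork, path: str | Path) -> None:
    """Write the canonical 3-column TSV (endpoints sorted, rows sorted).

    Confidences are written with ``repr`` so reading the file back
    reproduces the network exactly.
    """
    with open(path, "w") as fh:
        for a, b, c in net.edges():
            fh.write(f"{a}\t{b}\t{c!r}\n")


def filter_by_confidence(
    net: PPINetwork, threshold: float, keep_isolated: bool = False
) -> PPINetwork:
    """Keep edges with confidence strictly greater than ``threshold``.

    The strict inequality mirrors the usual "high confidence > 0.7"
    STRING filter. Nodes left without edges are removed unless
    ``keep_isolated`` is set. The threshold is recorded in metadata.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    g = nx.Graph()
    if keep_isolated:
        g.add_nodes_from(net.graph.nodes)
    for a, b, d in net.graph.edges(data=True):
        if d["confidence"] > threshold:
            g.add_edge(a, b, confidence=d["confidence"])
    meta = dict(net.metadata)
    meta["confidence_threshold"] = threshold
    return PPINetwork(g, meta)


def network_summary(net: PPINetwork) -> NetworkSummary:
    """Node/edge counts, density 2E/(V(V-1)), and component structure."""
    g = net.graph
    comps = list(nx.connected_components(g)) if g.number_of_nodes() else []
    return NetworkSummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        density=net.density(),
        n_components=len(comps),
        largest_component_size=max((len(c) for c in comps), default=0),
    )
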