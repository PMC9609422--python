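"""Seeded generators for networks, gene lists and annotations.

The interaction databases behind a network-pharmacology study cannot be
redistributed, so every pipeline stage is exercised against synthetic
inputs with the same statistical structure: a scale-free interaction
network at the scale of a confidence-filtered disease PPI network
(906 nodes, 9647 edges by default) carrying planted dense modules
(default sizes 79, 44 and 59 at the densities such modules show in
practice), a disease gene list of 1155 identifiers overlapping a
318-identifier compound-target list in exactly 96 genes, and GMT
annotation terms with optional planted enrichment in a query set.

All generators draw from a single ``numpy.random.default_rng`` stream
per call and iterate in fixed orders, so one seed gives byte-identical
outputs on every run and platform.

Ground truth (planted module memberships, the intended shared genes,
the enriched terms and query) is returned alongside each artefact so
recovery can be measured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .enrichment import AnnotationCollection
from .graph_core import PPINetwork
from .identifiers import GeneSet

__all__ = [
    "PlantedModule",
    "SyntheticConfig",
    "generate_network",
    "generate_gene_lists",
    "generate_annotations",
]


@dataclass(frozen=True)
class PlantedModule:
    """A dense block to embed: ``size`` nodes at within-block ``density``."""

    size: int
    density: float

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("planted module size must be >= 2")
        if not 0.0 < self.density <= 1.0:
            raise ValueError("planted module density must be in (0, 1]")

    @property
    def n_edges(self) -> int:
        return int(round(self.density * self.size * (self.size - 1) / 2))


def _default_modules() -> list[PlantedModule]:
    # Sizes and densities matching the three densest modules of a
    # filtered 906-node disease network: 79 nodes/881 edges,
    # 44/404, 59/287.
    return [
        PlantedModule(79, 881 / 3081),
        PlantedModule(44, 404 / 946),
        PlantedModule(59, 287 / 1711),
    ]


@dataclass
class SyntheticConfig:
    """Generation regime; defaults reproduce the reference study scale."""

    seed: int = 0
    n_nodes: int = 906
    target_edges: int = 9647
    planted_modules: list[PlantedModule] = field(default_factory=_default_modules)
    #: confidence of background edges: ("uniform", lo, hi) or ("beta", a, b).
    #: The default upper-tail uniform emulates a network already filtered
    #: at combined score > 0.7.
    confidence_dist: tuple = ("uniform", 0.701, 0.999)
    #: planted-module edges draw from this uniform range so a >0.7
    #: confidence filter never destroys planted structure
    module_confidence: tuple[float, float] = (0.72, 0.999)
    allow_intermodule_edges: bool = False
    disease_list_size: int = 1155
    target_list_size: int = 318
    overlap_count: int = 96
    n_terms: int = 40
    term_size_range: tuple[int, int] = (10, 80)
    query_size: int = 100
    #: list of (term_index, oversample_factor) planted enrichments
    enriched_terms: list[tuple[int, float]] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if sum(m.size for m in self.planted_modules) > self.n_nodes:
            raise ValueError("planted modules exceed the node budget")
        planted = sum(m.n_edges for m in self.planted_modules)
        if planted > self.target_edges:
            raise ValueError("planted modules alone exceed target_edges")
        if self.target_edges > self.n_nodes * (self.n_nodes - 1) // 2:
            raise ValueError("target_edges exceeds the simple-graph maximum")
        if self.overlap_count > min(self.disease_list_size, self.target_list_size):
            raise ValueError("overlap_count exceeds a list size")
        lo, hi = self.term_size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid term_size_range")
        for idx, factor in self.enriched_terms:
            if not 0 <= idx < self.n_terms or factor <= 0:
                raise ValueError(f"invalid enriched term ({idx}, {factor})")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_nodes": self.n_nodes,
            "target_edges": self.target_edges,
            "planted_modules": [
                {"size": m.size, "density": m.density} for m in self.planted_modules
            ],
            "confidence_dist": list(self.confidence_dist),
            "module_confidence": list(self.module_confidence),
            "allow_intermodule_edges": self.allow_intermodule_edges,
            "disease_list_size": self.disease_list_size,
            "target_list_size": self.target_list_size,
            "overlap_count": self.overlap_count,
            "n_terms": self.n_terms,
            "term_size_range": list(self.term_size_range),
            "query_size": self.query_size,
            "enriched_terms": [list(t) for t in self.enriched_terms],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "planted_modules" in d:
            d["planted_modules"] = [
                PlantedModule(m["size"], m["density"]) for m in d["planted_modules"]
            ]
        for key in ("confidence_dist", "module_confidence", "term_size_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "enriched_terms" in d:
            d["enriched_terms"] = [tuple(t) for t in d["enriched_terms"]]
        return cls(**d)


def _node_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _sample_confidence(rng: np.random.Generator, dist: tuple, size: int) -> np.ndarray:
    kind = dist[0]
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size)
    if kind == "beta":
        return rng.beta(dist[1], dist[2], size)
    raise ValueError(f"unknown confidence distribution {kind!r}")


def generate_network(cfg: SyntheticConfig) -> tuple[PPINetwork, dict]:
    """Scale-free background with planted dense modules.

    Module node sets are disjoint random subsets; each module is an
    Erdos-Renyi block realised with exactly ``round(density*C(size,2))``
    edges. The background is grown by preferential attachment (degree
    plus one) over a random arrival order, then topped up or thinned
    with uniform edges to hit ``target_edges`` exactly. Unless
    ``allow_intermodule_edges`` is set, background edges joining two
    distinct planted modules are rejected so module ground truth stays
    identifiable. Returns the network and the ground-truth record.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    names = _node_names(cfg.n_nodes)
    order = [names[i] for i in rng.permutation(cfg.n_nodes)]

    # planted modules on disjoint random node sets
    module_of: dict[str, int] = {}
    modules: list[list[str]] = []
    pos = 0
    for mi, mod in enumerate(cfg.planted_modules):
        members = sorted(order[pos:pos + mod.size])
        pos += mod.size
        modules.append(members)
        for v in members:
            module_of[v] = mi

    g = nx.Graph()
    g.add_nodes_from(names)
    module_edges: list[tuple[str, str]] = []
    for members, mod in zip(modules, cfg.planted_modules):
        pairs = [
            (members[i], members[j])
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ]
        chosen = rng.choice(len(pairs), size=mod.n_edges, replace=False)
        for idx in sorted(chosen):
            a, b = pairs[idx]
            g.add_edge(a, b)
            module_edges.append((a, b))

    def forbidden(a: str, b: str) -> bool:
        if cfg.allow_intermodule_edges:
            return False
        ma, mb = module_of.get(a), module_of.get(b)
        return ma is not None and mb is not None and ma != mb

    # preferential-attachment background over the arrival order
    remaining = cfg.target_edges - g.number_of_edges()
    n = cfg.n_nodes
    m_avg = remaining / max(n - 1, 1)
    base = int(m_avg)
    frac = m_avg - base
    attach: list[str] = [order[0]]  # degree-weighted endpoint pool
    for i in range(1, n):
        v = order[i]
        m_i = min(i, base + (1 if rng.random() < frac else 0))
        tries = 0
        added = 0
        while added < m_i and tries < 50 * (m_i + 1):
            u = attach[int(rng.integers(len(attach)))]
            tries += 1
            if u == v or g.has_edge(u, v) or forbidden(u, v):
                continue
            g.add_edge(u, v)
            attach.append(u)
            added += 1
        attach.append(v)

    # exact edge-count adjustment
    tries = 0
    while g.number_of_edges() < cfg.target_edges:
        i, j = rng.integers(n), rng.integers(n)
        tries += 1
        if tries > 200 * cfg.target_edges:
            raise ValueError("could not reach target_edges; config infeasible")
        a, b = names[int(i)], names[int(j)]
        if a == b or g.has_edge(a, b) or forbidden(a, b):
            continue
        g.add_edge(a, b)
    planted_set = set(map(frozenset, module_edges))
    if g.number_of_edges() > cfg.target_edges:
        removable = sorted(
            (min(a, b), max(a, b))
            for a, b in g.edges
            if frozenset((a, b)) not in planted_set
        )
        excess = g.number_of_edges() - cfg.target_edges
        for idx in rng.choice(len(removable), size=excess, replace=False):
            g.remove_edge(*removable[int(idx)])

    # confidences: background from cfg.confidence_dist, planted from the
    # upper tail so a high-confidence filter keeps planted structure
    bg_edges = sorted(
        (min(a, b), max(a, b)) for a, b in g.edges
        if frozenset((a, b)) not in planted_set
    )
    conf_bg = np.clip(
        _sample_confidence(rng, cfg.confidence_dist, len(bg_edges)), 0.0, 1.0
    )
    for (a, b), c in zip(bg_edges, conf_bg):
        g.edges[a, b]["confidence"] = float(c)
    lo, hi = cfg.module_confidence
    conf_mod = rng.uniform(lo, hi, len(module_edges))
    for (a, b), c in zip(sorted(module_edges), conf_mod):
        g.edges[a, b]["confidence"] = float(c)

    net = PPINetwork(g, {"generator": "synthetic", "config": cfg.to_dict()})
    truth = {"modules": [sorted(m) for m in modules]}
    return net, truth


def generate_gene_lists(
    net: PPINetwork, cfg: SyntheticConfig
) -> tuple[GeneSet, GeneSet, dict]:
    """Disease genes, compound targets and their engineered overlap.

    Disease genes are drawn from the network degree-biased (weight
    degree+1), emulating the hub enrichment of literature-curated
    disease lists; when the requested list is larger than the network
    the surplus is realised as off-network identifiers, mirroring the
    common situation where only part of a disease list maps into the
    PPI network. The target list shares exactly ``overlap_count``
    members with the disease list; the remainder is drawn from
    non-disease network nodes, then off-network identifiers.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    nodes = net.nodes()
    n = len(nodes)
    n_dis_net = min(cfg.disease_list_size, n)
    deg = np.array([net.graph.degree(v) for v in nodes], dtype=float) + 1.0
    picked = rng.choice(n, size=n_dis_net, replace=False, p=deg / deg.sum())
    disease = {nodes[int(i)] for i in picked}
    disease |= {f"D{i:04d}" for i in range(cfg.disease_list_size - n_dis_net)}

    disease_sorted = sorted(disease)
    shared_idx = rng.choice(
        len(disease_sorted), size=cfg.overlap_count, replace=False
    )
    shared = {disease_sorted[int(i)] for i in shared_idx}
    pool = [v for v in nodes if v not in disease]
    need = cfg.target_list_size - cfg.overlap_count
    if len(pool) >= need:
        others_idx = rng.choice(len(pool), size=need, replace=False)
        others = {pool[int(i)] for i in others_idx}
    else:
        others = set(pool)
        others |= {f"T{i:04d}" for i in range(need - len(pool))}
    targets = shared | others

    return (
        GeneSet.from_strings("disease_genes", disease),
        GeneSet.from_strings("compound_targets", targets),
        {"shared": sorted(shared)},
    )


def generate_annotations(
    net: PPINetwork, cfg: SyntheticConfig
) -> tuple[AnnotationCollection, GeneSet, dict]:
    """Annotation terms over the network universe plus a query set.

    Terms are uniform random subsets of the node universe. The query
    emulates a gene list enriched for particular terms: members of each
    planted term enter the query with probability
    ``min(1, factor * query_size/N)`` — i.e. at ``factor`` times the base
    inclusion rate — and the remainder of the query is drawn uniformly
    from the rest of the universe. A factor of 1 is therefore the null.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 2)
    universe = net.nodes()
    n = len(universe)
    lo, hi = cfg.term_size_range
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    member_lists: list[frozenset[str]] = []
    for i in range(cfg.n_terms):
        size = int(rng.integers(lo, min(hi, n) + 1))
        idx = rng.choice(n, size=size, replace=False)
        members = frozenset(universe[int(j)] for j in idx)
        terms[f"T{i:03d}"] = (f"synthetic term {i}", members)
        member_lists.append(members)

    q_size = min(cfg.query_size, n)
    base_rate = q_size / n
    chosen: set[str] = set()
    for idx, factor in cfg.enriched_terms:
        rate = min(1.0, factor * base_rate)
        for v in sorted(member_lists[idx]):
            if v not in chosen and rng.random() < rate:
                chosen.add(v)
    if len(chosen) > q_size:
        keep = rng.choice(sorted(chosen), size=q_size, replace=False)
        chosen = set(keep)
    pool = [v for v in universe if v not in chosen]
    fill = rng.choice(len(pool), size=q_size - len(chosen), replace=False)
    query = GeneSet.from_strings(
        "query", chosen | {pool[int(i)] for i in fill}
    )

    collection = AnnotationCollection.from_terms(
        {t: (nm, m) for t, (nm, m) in terms.items()}, background=universe
    )
    truth = {
        "enriched_terms": [
            {"term_id": f"T{idx:03d}", "factor": factor}
            for idx, factor in cfg.enriched_terms
        ],
        "query": sorted(query.keys()),
    }
    return collection, query, truth


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))
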