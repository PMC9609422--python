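"""Identifier normalisation, Venn intersections and target-coverage statistics.

This stage answers the network-pharmacology question proper: how much of
a disease's gene neighbourhood does a compound's target list reach? It
runs in three phases — compound targets against (1) all disease genes,
(2) the hub candidates / hub genes, and (3) each detected MCODE module —
after reconciling every list to one identifier namespace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from .identifiers import GeneId, GeneSet
from .mcode import MCODECluster

__all__ = [
    "NormalizationReport",
    "VennResult",
    "CoverageStat",
    "read_mapping",
    "normalize_ids",
    "intersect",
    "venn3",
    "coverage",
    "cluster_coverage",
]


@dataclass(frozen=True)
class NormalizationReport:
    n_input: int
    n_mapped: int
    n_merged: int
    unmapped: frozenset[str]


def read_mapping(path: str | Path) -> dict[str, str]:
    """Two-column TSV source->canonical accession; '#' lines are comments.

    Repeated source keys are allowed only when they agree; a source key
    mapped to two different accessions is an error.
    """
    mapping: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        src, dst = fields[0], fields[1]
        if src in mapping and mapping[src] != dst:
            raise ValueError(
                f"{path}:{lineno}: conflicting mapping for {src!r}: "
                f"{mapping[src]!r} vs {dst!r}"
            )
        mapping[src] = dst
    return mapping


def normalize_ids(
    raw: GeneSet,
    mapping: dict[str, str],
    namespace: str = "canonical",
    strict: bool = False,
) -> tuple[GeneSet, NormalizationReport]:
    """Replace identifiers by canonical accessions; merge resulting aliases.

    Unmapped identifiers are retained verbatim (conservative set sizes)
    and listed in the report; ``strict`` drops them instead.
    """
    mapped: set[GeneId] = set()
    unmapped: list[str] = []
    n_mapped = 0
    for gid in raw.ids:
        target = mapping.get(gid.key, mapping.get(gid.symbol))
        if target is not None:
            mapped.add(GeneId(gid.symbol, accession=target))
            n_mapped += 1
        else:
            unmapped.append(gid.key)
            if not strict:
                mapped.add(GeneId(gid.symbol))
    n_contributing = n_mapped if strict else len(raw)
    report = NormalizationReport(
        n_input=len(raw),
        n_mapped=n_mapped,
        n_merged=n_contributing - len(mapped),
        unmapped=frozenset(unmapped),
    )
    return GeneSet(raw.label, frozenset(mapped), namespace), report


@dataclass(frozen=True)
class VennResult:
    """Region counts of a 2- or 3-set Venn partition.

    Region signatures are membership bitmasks over the labelled sets in
    order, e.g. ``"110"`` = in the first two sets but not the third.
    ``shared`` is the all-sets intersection.
    """

    set_labels: tuple[str, ...]
    region_counts: dict[str, int]
    regions: dict[str, frozenset[str]]
    shared: GeneSet

    def to_dict(self) -> dict:
        return {
            "set_labels": list(self.set_labels),
            "region_counts": dict(sorted(self.region_counts.items())),
            "regions": {k: sorted(v) for k, v in sorted(self.regions.items())},
            "shared": sorted(self.shared.keys()),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _venn(sets: list[GeneSet]) -> VennResult:
    for s in sets[1:]:
        sets[0]._check_namespace(s)
    keysets = [s.keys() for s in sets]
    universe = frozenset().union(*keysets)
    regions: dict[str, set[str]] = {}
    for item in universe:
        sig = "".join("1" if item in ks else "0" for ks in keysets)
        regions.setdefault(sig, set()).add(item)
    shared_keys = frozenset.intersection(*keysets)
    shared_ids = frozenset(g for g in sets[0].ids if g.key in shared_keys)
    return VennResult(
        set_labels=tuple(s.label for s in sets),
        region_counts={sig: len(v) for sig, v in regions.items()},
        regions={sig: frozenset(v) for sig, v in regions.items()},
        shared=GeneSet(
            "&".join(s.label for s in sets), shared_ids, sets[0].namespace
        ),
    )


def intersect(a: GeneSet, b: GeneSet) -> VennResult:
    """Pairwise Venn partition: a-only, b-only, and the shared set."""
    return _venn([a, b])


def venn3(a: GeneSet, b: GeneSet, c: GeneSet) -> VennResult:
    """Three-set Venn partition with bitmask region signatures."""
    return _venn([a, b, c])


@dataclass(frozen=True)
class CoverageStat:
    numerator: int
    denominator: int
    percent: float

    def __str__(self) -> str:
        return f"{self.numerator}/{self.denominator} = {self.percent:.2f}%"


def _round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("1." + "0" * ndigits),
                                           rounding=ROUND_HALF_UP))


def coverage(shared: GeneSet, reference: GeneSet) -> CoverageStat:
    """Percent of ``reference`` reached by ``shared``, half-up at 2 d.p."""
    if len(reference) == 0:
        raise ValueError("reference set must be non-empty")
    num = len(shared.keys() & reference.keys())
    den = len(reference)
    return CoverageStat(num, den, _round_half_up(100.0 * num / den))


def cluster_coverage(
    clusters: list[MCODECluster], targets: GeneSet
) -> list[dict]:
    """Per-cluster overlap with a target list.

    For each cluster (in given rank order): the number of members hit by
    the targets and the percentage of the cluster covered.
    """
    tkeys = targets.keys()
    out = []
    for rank, c in enumerate(clusters, start=1):
        hit = len(c.members & tkeys)
        pct = _round_half_up(100.0 * hit / c.n_nodes) if c.n_nodes else 0.0
        out.append(
            {
                "rank": rank,
                "seed": c.seed,
                "n_nodes": c.n_nodes,
                "n_targeted": hit,
                "percent_covered": pct,
            }
        )
    return out
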