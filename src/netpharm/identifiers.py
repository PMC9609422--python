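"""Gene/protein identifiers and identifier sets.

Interaction databases mix gene symbols, synonyms and accessions; every
set operation downstream (Venn intersections, coverage statistics) is
only meaningful after identifiers have been reconciled to one namespace.
A :class:`GeneId` therefore carries the raw symbol it was read with and,
once normalisation has run, a canonical accession; equality and hashing
use the accession when present so that aliases collapse to one identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


@dataclass(frozen=True, eq=False)
class GeneId:
    """A gene/protein identifier.

    Parameters
    ----------
    symbol : str
        The identifier as read from the input (case preserved). Must be a
        non-empty token without whitespace.
    accession : str, optional
        Canonical accession assigned by identifier normalisation. When
        set, it defines the identity of the object.
    """

    symbol: str
    accession: str | None = None

    def __post_init__(self) -> None:
        if not self.symbol or any(c.isspace() for c in self.symbol):
            raise ValueError(f"invalid gene symbol: {self.symbol!r}")
        if self.accession is not None and (
            not self.accession or any(c.isspace() for c in self.accession)
        ):
            raise ValueError(f"invalid accession: {self.accession!r}")

    @property
    def key(self) -> str:
        """Canonical identity: the accession when set, else the symbol."""
        return self.accession if self.accession is not None else self.symbol

    def __eq__(self, other: object) -> bool:
        if isinstance(other, GeneId):
            return self.key == other.key
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.key)

    def __str__(self) -> str:
        return self.key


@dataclass(frozen=True)
class GeneSet:
    """A labelled, duplicate-free set of :class:`GeneId`.

    ``namespace`` records which identifier namespace the set lives in
    (e.g. ``"uniprot"`` after normalisation); set operations between
    sets in explicitly different namespaces are refused.
    """

    label: str
    ids: frozenset[GeneId] = field(default_factory=frozenset)
    namespace: str | None = None

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("GeneSet label must be non-empty")
        object.__setattr__(self, "ids", frozenset(self.ids))

    @classmethod
    def from_strings(
        cls, label: str, symbols: Iterable[str], namespace: str | None = None
    ) -> "GeneSet":
        return cls(label, frozenset(GeneId(s) for s in symbols), namespace)

    @classmethod
    def from_file(cls, path: str | Path, label: str | None = None) -> "GeneSet":
        """Read a one-identifier-per-line list; '#' lines are comments."""
        path = Path(path)
        symbols = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            symbols.append(line.split()[0])
        return cls.from_strings(label or path.stem, symbols)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("".join(f"{k}\n" for k in sorted(self.keys())))

    def keys(self) -> frozenset[str]:
        """Canonical identifier strings."""
        return frozenset(g.key for g in self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[GeneId]:
        return iter(self.ids)

    def __contains__(self, item: object) -> bool:
        if isinstance(item, str):
            return item in self.keys()
        return item in self.ids

    def _check_namespace(self, other: "GeneSet") -> None:
        if (
            self.namespace is not None
            and other.namespace is not None
            and self.namespace != other.namespace
        ):
            raise ValueError(
                f"namespace mismatch: {self.namespace!r} vs {other.namespace!r}"
            )

    def union(self, other: "GeneSet", label: str | None = None) -> "GeneSet":
        self._check_namespace(other)
        return GeneSet(
            label or f"{self.label}|{other.label}",
            self.ids | other.ids,
            self.namespace or other.namespace,
        )

    def intersection(self, other: "GeneSet", label: str | None = None) -> "GeneSet":
        self._check_namespace(other)
        return GeneSet(
            label or f"{self.label}&{other.label}",
            self.ids & other.ids,
            self.namespace or other.namespace,
        )

    def difference(self, other: "GeneSet", label: str | None = None) -> "GeneSet":
        self._check_namespace(other)
        return GeneSet(
            label or f"{self.label}-{other.label}",
            self.ids - other.ids,
            self.namespace,
        )
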