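"""Hypergeometric over-representation analysis over GMT annotation sets.

For a query gene set of size n drawn from a background universe of size
N, and an annotation term with K members, the raw enrichment p-value is
the one-sided hypergeometric tail

    p = P[X >= k],   X ~ Hypergeometric(N, K, n),

where k is the observed query/term overlap. Alongside the p-value the
"associated genes %" statistic 100*k/K reports what share of the term the
query reaches. P-values are adjusted for multiplicity with Holm's
step-down procedure by default (the "Bonferroni step down" familiar from
ClueGO); Bonferroni and Benjamini-Hochberg are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .identifiers import GeneSet

__all__ = [
    "AnnotationCollection",
    "read_gmt",
    "write_gmt",
    "associated_percent",
    "adjust_pvalues",
    "hypergeometric_enrich",
]

_METHODS = {"holm": "holm", "bonferroni": "bonferroni", "bh": "fdr_bh"}


@dataclass(frozen=True)
class AnnotationCollection:
    """Named annotation terms over a background gene universe.

    ``terms`` maps term id to ``(name, members)``; every member belongs
    to ``background``, and empty terms are rejected. The background
    defaults to the union of all term members unless supplied.
    """

    terms: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for tid, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {tid!r} has no members")
            if not members <= self.background:
                raise ValueError(f"term {tid!r} has members outside the background")

    @classmethod
    def from_terms(
        cls,
        terms: Mapping[str, tuple[str, Iterable[str]]],
        background: Iterable[str] | None = None,
    ) -> "AnnotationCollection":
        tdict = {t: (name, frozenset(m)) for t, (name, m) in terms.items()}
        if background is None:
            bg: frozenset[str] = frozenset().union(
                *(m for _, m in tdict.values())
            ) if tdict else frozenset()
        else:
            bg = frozenset(background)
        return cls(tdict, bg)

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(
    path: str | Path, background: Iterable[str] | None = None
) -> AnnotationCollection:
    """Read GMT: term_id <TAB> description <TAB> member1 <TAB> member2 ..."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT row needs id, description, members")
        terms[fields[0]] = (fields[1], frozenset(f for f in fields[2:] if f))
    return AnnotationCollection.from_terms(
        {t: (n, m) for t, (n, m) in terms.items()}, background
    )


def write_gmt(collection: AnnotationCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(collection.terms):
            name, members = collection.terms[tid]
            fh.write("\t".join([tid, name, *sorted(members)]) + "\n")


def associated_percent(k: int, K: int) -> float:
    """Share of a K-member term present in the query: 100*k/K."""
    if K < 1:
        raise ValueError("term size K must be >= 1")
    if not 0 <= k <= K:
        raise ValueError("overlap k must satisfy 0 <= k <= K")
    return 100.0 * k / K


def adjust_pvalues(p_list: Iterable[float], method: str = "holm") -> np.ndarray:
    """Multiplicity-adjusted p-values in the original order, clipped at 1."""
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    if method not in _METHODS:
        raise ValueError(f"method must be one of {sorted(_METHODS)}")
    return np.minimum(multipletests(p, method=_METHODS[method])[1], 1.0)


def hypergeometric_enrich(
    query: GeneSet | Iterable[str],
    annotations: AnnotationCollection,
    min_overlap: int = 3,
    method: str = "holm",
) -> pd.DataFrame:
    """One-sided over-representation test for every annotation term.

    Query genes outside the background are dropped (and counted in the
    DataFrame attrs); terms overlapping the query by fewer than
    ``min_overlap`` genes are omitted. Rows are sorted by adjusted then
    raw p-value, ties by term id.

    Columns: term_id, name, k, K, n, N, associated_percent, p_raw,
    p_adjusted.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    qkeys = query.keys() if isinstance(query, GeneSet) else frozenset(query)
    if not qkeys:
        raise ValueError("query set is empty")
    if not annotations.background:
        raise ValueError("annotation background is empty")
    dropped = qkeys - annotations.background
    q = qkeys & annotations.background
    if not q:
        raise ValueError("no query gene is in the annotation background")

    N, n = len(annotations.background), len(q)
    rows = []
    for tid in sorted(annotations.terms):
        name, members = annotations.terms[tid]
        K = len(members)
        k = len(q & members)
        if k < min_overlap:
            continue
        rows.append(
            {
                "term_id": tid,
                "name": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "associated_percent": associated_percent(k, K),
                "p_raw": float(hypergeom.sf(k - 1, N, K, n)),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term_id", "name", "k", "K", "n", "N",
            "associated_percent", "p_raw",
        ],
    )
    if len(df):
        df["p_adjusted"] = adjust_pvalues(df["p_raw"], method)
        df = df.sort_values(
            ["p_adjusted", "p_raw", "term_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    df.attrs["n_query_dropped"] = len(dropped)
    df.attrs["adjustment"] = method
    return df
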