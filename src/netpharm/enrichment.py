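"""Over-representation analysis (ORA) with Bonferroni family-wise control.

A query gene set (typically the members of one detected network module) is
tested against every term of an annotation catalog. For a term with K
annotated genes, a query of n genes within a universe of N, and an observed
overlap of k, the raw p-value is the hypergeometric upper tail
P(X >= k). Two variants are offered:

- ``hypergeom`` — the plain upper tail;
- ``ease`` — the conservative variant that evaluates the tail at k - 1
  (the score many annotation servers report).

Raw p-values are Bonferroni-adjusted by the number of terms actually tested
for that query (terms with k >= 1), and a term is called significant when
its adjusted p falls below alpha (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from . import io as npio

__all__ = [
    "AnnotationCatalog",
    "hypergeom_upper",
    "ease_score",
    "bonferroni_adjust",
    "enrich",
]

RESULT_COLUMNS = (
    "term_id", "term_name", "k", "K", "n", "N", "p_raw", "p_bonferroni", "significant",
)


@dataclass(frozen=True)
class AnnotationCatalog:
    """Gene-set catalog: term_id -> (name, gene set) over a fixed universe.

    The universe defaults to the union of all term gene sets (every
    annotated gene); an explicit, larger universe may be supplied. One
    annotation namespace (e.g. biological process) per catalog is assumed.
    """

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    @classmethod
    def from_terms(cls, terms, universe=None) -> "AnnotationCatalog":
        terms = {t: (name, frozenset(genes)) for t, (name, genes) in terms.items()}
        annotated = frozenset().union(*(g for _, g in terms.values())) if terms else frozenset()
        uni = frozenset(universe) if universe is not None else annotated
        for t, (_, genes) in terms.items():
            if not genes:
                raise ValueError(f"term {t} has an empty gene set")
            if not genes <= uni:
                raise ValueError(f"term {t} has genes outside the universe")
        return cls(terms, uni)

    @classmethod
    def from_gmt(cls, path, universe=None) -> "AnnotationCatalog":
        return cls.from_terms(npio.read_gmt(path), universe)

    def to_gmt(self, path) -> None:
        npio.write_gmt(self.terms, path)


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the term-set size, n the query size, k the
    observed overlap. ``k = 0`` gives exactly 1.
    """
    _check_counts(k, K, n, N)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def ease_score(k: int, K: int, n: int, N: int) -> float:
    """Conservative ORA score: the upper tail evaluated at k - 1.

    Equals ``hypergeom_upper(k - 1, K, n, N)`` and is therefore never
    smaller than the plain score; requires k >= 1.
    """
    _check_counts(k, K, n, N)
    if k < 1:
        raise ValueError("EASE score requires at least one overlapping gene")
    return hypergeom_upper(k - 1, K, n, N)


def bonferroni_adjust(p_values, m: int) -> list[float]:
    """min(1, p * m) for each raw p; m is the number of tests in the family."""
    p_values = list(p_values)
    if m < len(p_values):
        raise ValueError(f"multiplier m={m} smaller than number of p-values ({len(p_values)})")
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value out of range: {p}")
        out.append(min(1.0, p * m))
    return out


def enrich(
    query_genes,
    catalog: AnnotationCatalog,
    method: str = "hypergeom",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test a query gene set against every catalog term.

    The query is first restricted to the catalog universe (genes outside it
    carry no annotation information). One row is emitted per term with
    overlap k >= 1; the Bonferroni multiplier is the number of such terms.
    Rows are sorted by adjusted p ascending, then term_id.

    Raises
    ------
    ValueError
        If the restricted query is empty, or ``method`` is unknown.
    """
    if method not in ("hypergeom", "ease"):
        raise ValueError(f"unknown method {method!r}")
    score = hypergeom_upper if method == "hypergeom" else ease_score
    query = set(query_genes) & set(catalog.universe)
    if not query:
        raise ValueError("query has no genes in the annotation universe")
    n, N = len(query), len(catalog.universe)

    rows = []
    for term_id in sorted(catalog.terms):
        name, genes = catalog.terms[term_id]
        k = len(query & genes)
        if k == 0:
            continue
        rows.append((term_id, name, k, len(genes), n, N, score(k, len(genes), n, N)))
    m = len(rows)
    result = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p_raw"])
    result["p_bonferroni"] = bonferroni_adjust(result["p_raw"], m) if m else []
    result["significant"] = result["p_bonferroni"] < alpha
    return result.sort_values(
        ["p_bonferroni", "term_id"], ignore_index=True
    )
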