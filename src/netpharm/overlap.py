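"""Drug-disease overlap of enriched biological processes, by etiology.

The drug side and the disease side of the analysis each yield a set of
significantly enriched biological-process terms (union over their network
modules). The intersection of the two sets is the group of processes the
formula may regulate *directly*; each overlapping term is then assigned to a
named disease-etiology category (e.g. endothelial cell activation and
injury) via an :class:`EtiologyMapping`, or left unassigned.

A default mapping for pregnancy-induced hypertension ships with the package
(``data/etiology_pih.yaml``); it is data, not code, and users may supply
their own.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

__all__ = ["EtiologyMapping", "OverlapReport", "collect_significant", "overlap_terms", "partition_by_etiology"]


@dataclass(frozen=True)
class EtiologyMapping:
    """Named etiology categories, each holding a disjoint set of term ids."""

    categories: dict[str, frozenset[str]]

    def __post_init__(self):
        seen: dict[str, str] = {}
        for cat, terms in self.categories.items():
            for t in terms:
                if t in seen:
                    raise ValueError(
                        f"term {t} assigned to both {seen[t]!r} and {cat!r}"
                    )
                seen[t] = cat

    @classmethod
    def from_dict(cls, mapping: dict) -> "EtiologyMapping":
        return cls({str(c): frozenset(map(str, ts)) for c, ts in mapping.items()})

    @classmethod
    def from_yaml(cls, path) -> "EtiologyMapping":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of category -> term list")
        return cls.from_dict(data)

    @classmethod
    def default_pih(cls) -> "EtiologyMapping":
        """The packaged pregnancy-induced-hypertension mapping."""
        ref = importlib.resources.files("netpharm.data").joinpath("etiology_pih.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text()))

    def category_of(self, term: str) -> str | None:
        for cat, terms in self.categories.items():
            if term in terms:
                return cat
        return None


@dataclass(frozen=True)
class OverlapReport:
    """Outcome of the drug/disease term intersection and its partition."""

    drug_terms: frozenset[str]
    disease_terms: frozenset[str]
    overlap: frozenset[str]
    per_category_counts: dict[str, int]
    per_category_terms: dict[str, frozenset[str]]
    unassigned: frozenset[str]

    def to_dict(self) -> dict:
        return {
            "drug_terms": sorted(self.drug_terms),
            "disease_terms": sorted(self.disease_terms),
            "overlap": sorted(self.overlap),
            "per_category_counts": dict(self.per_category_counts),
            "per_category_terms": {c: sorted(t) for c, t in self.per_category_terms.items()},
            "unassigned": sorted(self.unassigned),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat, terms in self.per_category_terms.items():
            for t in sorted(terms):
                rows.append((t, cat))
        for t in sorted(self.unassigned):
            rows.append((t, "unassigned"))
        return pd.DataFrame(rows, columns=["term_id", "category"])


def collect_significant(enrichment_tables) -> frozenset[str]:
    """Union of significant term ids over the enrichment tables of one side."""
    terms: set[str] = set()
    for table in enrichment_tables:
        if "significant" not in table.columns or "term_id" not in table.columns:
            raise ValueError("enrichment table lacks term_id/significant columns")
        terms.update(table.loc[table["significant"].astype(bool), "term_id"])
    return frozenset(terms)


def overlap_terms(drug_terms, disease_terms) -> frozenset[str]:
    """Exact set intersection of drug-side and disease-side term sets."""
    return frozenset(drug_terms) & frozenset(disease_terms)


def partition_by_etiology(
    drug_terms, disease_terms, mapping: EtiologyMapping
) -> OverlapReport:
    """Intersect the two term sets and split the overlap by etiology category.

    Every overlapping term lands either in exactly one category or in
    ``unassigned``; counts therefore sum to the overlap size.
    """
    drug = frozenset(drug_terms)
    disease = frozenset(disease_terms)
    shared = drug & disease
    per_cat = {cat: shared & terms for cat, terms in mapping.categories.items()}
    assigned = frozenset().union(*per_cat.values()) if per_cat else frozenset()
    return OverlapReport(
        drug_terms=drug,
        disease_terms=disease,
        overlap=shared,
        per_category_counts={c: len(t) for c, t in per_cat.items()},
        per_category_terms=per_cat,
        unassigned=shared - assigned,
    )
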