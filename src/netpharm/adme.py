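"""ADME compound triage: Tanimoto drug-likeness and the three-threshold filter.

Candidate compounds of a herbal formula are screened on three precomputed
pharmacokinetic properties: oral bioavailability (OB, a percentage),
Caco-2 cell-monolayer permeability (a dimensionless in-silico score), and
drug-likeness (DL). DL is the Tanimoto similarity between a compound's
molecular-descriptor vector and an average-drug reference vector:

    f(x, y) = x.y / (|x|^2 + |y|^2 - x.y)

A compound is retained when OB >= ob_min, Caco-2 > caco2_min and
DL >= dl_min (defaults 30, -0.4, 0.18; note Caco-2 is a strict bound while
the other two are inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterThresholds",
    "dl_score",
    "dl_scores_from_descriptors",
    "apply_adme_filter",
]

#: Columns every compound property table must carry.
REQUIRED_COLUMNS = ("compound_id", "name", "herb", "ob", "caco2", "dl")


@dataclass(frozen=True)
class FilterThresholds:
    """Inclusion thresholds for the ADME filter.

    ob_min and dl_min are inclusive lower bounds; caco2_min is exclusive.
    """

    ob_min: float = 30.0
    caco2_min: float = -0.4
    dl_min: float = 0.18


def dl_score(x, y) -> float:
    """Tanimoto drug-likeness of descriptor vector ``x`` against reference ``y``.

    Both vectors must be non-negative, of equal dimension, and not both zero;
    the score is symmetric and lies in [0, 1] (Cauchy-Schwarz:
    x.y <= |x||y| <= max(|x|^2, |y|^2), so the denominator dominates the
    numerator for non-negative inputs).

    Raises
    ------
    ValueError
        On dimension mismatch, negative components, or two zero vectors
        (the score is undefined at 0/0).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"descriptor dimension mismatch: {x.size} vs {y.size}")
    if x.size == 0:
        raise ValueError("empty descriptor vector")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("descriptor components must be non-negative")
    dot = float(x @ y)
    denom = float(x @ x) + float(y @ y) - dot
    if denom == 0.0:
        # only possible when x == y == 0
        raise ValueError("drug-likeness undefined for two zero vectors")
    return dot / denom


def dl_scores_from_descriptors(descriptors: pd.DataFrame, reference) -> pd.Series:
    """Row-wise :func:`dl_score` of a descriptor table against one reference.

    ``descriptors`` is indexed by compound_id with one column per molecular
    parameter; ``reference`` is the average-drug vector of identical dimension.
    """
    ref = np.asarray(reference, dtype=float).ravel()
    if descriptors.shape[1] != ref.size:
        raise ValueError(
            f"descriptor dimension mismatch: table has {descriptors.shape[1]}, "
            f"reference has {ref.size}"
        )
    return pd.Series(
        [dl_score(row, ref) for row in descriptors.to_numpy(dtype=float)],
        index=descriptors.index,
        name="dl",
    )


def _first_failure(row, th: FilterThresholds) -> str | None:
    # checked in the order the rule is stated: OB, Caco-2, DL
    if row.ob < th.ob_min:
        return "ob"
    if row.caco2 <= th.caco2_min:
        return "caco2"
    if row.dl < th.dl_min:
        return "dl"
    return None


def apply_adme_filter(
    table: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the three-threshold inclusion rule to a compound table.

    Returns ``(retained, excluded)``; ``excluded`` carries a
    ``failed_criterion`` column naming the first failing property (checked
    in order ob, caco2, dl). Every input row lands in exactly one output.

    Raises
    ------
    ValueError
        If a required column is missing or any ob/caco2/dl value is null —
        records with missing properties are an error, never a silent drop.
    """
    th = thresholds or FilterThresholds()
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"compound table missing columns: {missing}")
    props = table[["ob", "caco2", "dl"]]
    if props.isna().any().any():
        bad = table.loc[props.isna().any(axis=1), "compound_id"].tolist()
        raise ValueError(f"compounds with missing ADME properties: {bad}")

    failures = [
        _first_failure(row, th)
        for row in table[["ob", "caco2", "dl"]].itertuples(index=False)
    ]
    keep = pd.Series([f is None for f in failures], index=table.index)
    retained = table.loc[keep].copy()
    excluded = table.loc[~keep].copy()
    excluded["failed_criterion"] = [f for f in failures if f is not None]
    return retained, excluded
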