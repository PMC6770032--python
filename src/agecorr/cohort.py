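"""Clinical-cohort composition tables: counts and percentages per age group.

Produces the standard clinico-pathological summary layout: for one
categorical attribute, the count and within-column percentage overall and in
each age group (PEDS, AYA).  Missing values form their own ``NA`` category.
Percentages round to the nearest integer, ties away from zero — e.g. a 9/21
cell prints 43.
"""

from __future__ import annotations

import math

import pandas as pd

from .io import AGE_GROUPS

__all__ = ["read_clinical", "summarize", "summarize_all", "round_half_away"]

NA_LABEL = "NA"
_RESERVED = ("sample_id", "age_group")


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (not banker's rounding)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical CSV/TSV with sample_id, age_group and attribute columns."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    for col in _RESERVED:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    bad = set(df["age_group"].dropna()) - set(AGE_GROUPS)
    if bad:
        raise ValueError(
            f"unknown age_group value(s) {sorted(bad)}; accepted: {', '.join(AGE_GROUPS)}"
        )
    return df


def summarize(records: pd.DataFrame, attribute: str) -> pd.DataFrame:
    """Composition table for one attribute.

    Returns one row per category with columns ``category, n_all, pct_all,
    n_PEDS, pct_PEDS, n_AYA, pct_AYA``; percentages use the column total as
    denominator.  Categories are ordered by first appearance, NA last.
    """
    if attribute in _RESERVED or attribute not in records.columns:
        raise KeyError(f"unknown attribute {attribute!r}")
    values = records[attribute].fillna(NA_LABEL).replace("", NA_LABEL)
    categories = [c for c in values.unique() if c != NA_LABEL]
    if (values == NA_LABEL).any():
        categories.append(NA_LABEL)

    def column(mask):
        sub = values[mask]
        total = len(sub)
        counts = [(sub == c).sum() for c in categories]
        pcts = [round_half_away(100.0 * c / total) if total else 0 for c in counts]
        return counts, pcts

    n_all, pct_all = column(pd.Series(True, index=records.index))
    out = {"category": categories, "n_all": n_all, "pct_all": pct_all}
    for grp in AGE_GROUPS:
        n, pct = column(records["age_group"] == grp)
        out[f"n_{grp}"] = n
        out[f"pct_{grp}"] = pct
    return pd.DataFrame(out)


def summarize_all(records: pd.DataFrame) -> dict:
    """Summaries for every non-reserved attribute column."""
    return {
        col: summarize(records, col)
        for col in records.columns
        if col not in _RESERVED
    }
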