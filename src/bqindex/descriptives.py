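"""Descriptive surfaces: top breakfast contributors, consumer prevalence,
component prevalence across score categories, and score summaries.

All percentages are kept at full precision internally; the rendering helpers
round to one decimal, matching the usual presentation of survey tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_model import BQIResult, Cohort
from .taxonomy import Taxonomy, group_grams

__all__ = [
    "PrevalenceTable",
    "contribution_shares",
    "consumer_prevalence",
    "component_prevalence",
    "score_summary",
]

CATEGORY_ORDER = ("low", "medium", "high")


def contribution_shares(cohort: Cohort, taxonomy: Taxonomy, k: int = 5) -> pd.DataFrame:
    """Top-k reporting groups by share of total breakfast grams.

    Shares are group grams / total breakfast grams x 100, over the whole
    cohort (non-consumers contribute zero grams); over all groups they sum
    to 100.
    """
    grams = group_grams(cohort, taxonomy)
    total = grams.sum()
    if total <= 0:
        raise ValueError("no breakfast grams in cohort; cannot compute shares")
    shares = (grams / total * 100.0).sort_values(ascending=False)
    out = pd.DataFrame({"grams": grams.reindex(shares.index), "share_pct": shares})
    out.index.name = "reporting_group"
    return out.head(k)


def consumer_prevalence(cohort: Cohort, taxonomy: Taxonomy) -> pd.Series:
    """% of participants consuming each reporting group at breakfast."""
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")
    counts: dict[str, int] = {}
    for day in cohort.days.values():
        bkf = day.breakfast()
        if bkf is None:
            continue
        for group in {taxonomy.group_of(item.food_code) for item in bkf.items}:
            counts[group] = counts.get(group, 0) + 1
    prev = pd.Series(counts, dtype=float) / n * 100.0
    prev.index.name = "reporting_group"
    return prev.sort_values(ascending=False)


@dataclass(frozen=True)
class PrevalenceTable:
    """Component prevalence (% scoring 1) overall and within categories.

    ``table`` has one row per component and columns total/low/medium/high;
    ``n`` and ``mean``/``sd`` describe each column's participants.  Empty
    categories keep their column with N = 0 and NaN cells.
    """

    table: pd.DataFrame
    n: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]


def component_prevalence(results: Mapping[str, BQIResult]) -> PrevalenceTable:
    """Tabulate per-component pass rates overall and across score categories."""
    if not results:
        raise ValueError("no scored participants")
    component_names = list(next(iter(results.values())).components)
    rows = []
    for res in results.values():
        row = {name: bool(res.components[name]) for name in component_names}
        row["score"] = res.score
        row["category"] = res.category
        rows.append(row)
    df = pd.DataFrame(rows)

    cols: dict[str, pd.Series] = {}
    n: dict[str, int] = {}
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    subsets = {"total": df, **{c: df[df["category"] == c] for c in CATEGORY_ORDER}}
    for name, sub in subsets.items():
        n[name] = len(sub)
        if len(sub):
            cols[name] = sub[component_names].mean() * 100.0
            mean[name] = float(sub["score"].mean())
            sd[name] = float(sub["score"].std(ddof=1)) if len(sub) > 1 else 0.0
        else:
            cols[name] = pd.Series(np.nan, index=component_names)
            mean[name] = float("nan")
            sd[name] = float("nan")
    table = pd.DataFrame(cols)
    table.index.name = "component"
    return PrevalenceTable(table=table, n=n, mean=mean, sd=sd)


def score_summary(results: Mapping[str, BQIResult]) -> dict:
    """n, mean, sample SD (n-1), min/max and category shares of the scores.

    With a single participant the SD is reported as 0.0 with
    ``sd_defined = False``.
    """
    if not results:
        raise ValueError("no scored participants")
    scores = np.array([res.score for res in results.values()], dtype=float)
    cats = pd.Series([res.category for res in results.values()])
    n = len(scores)
    shares = {c: float((cats == c).mean() * 100.0) for c in CATEGORY_ORDER}
    return {
        "n": n,
        "mean": float(scores.mean()),
        "sd": float(scores.std(ddof=1)) if n > 1 else 0.0,
        "sd_defined": n > 1,
        "min": float(scores.min()),
        "max": float(scores.max()),
        "category_shares_pct": shares,
    }
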