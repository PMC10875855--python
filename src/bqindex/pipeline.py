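"""Cohort-level scoring: ties the per-day scorers to the data model.

Adult scoring is a single pass; child scoring is two-pass because the
MUFA:SFA criterion is relative to the cohort median, which is computed
exactly once per run.
"""

from __future__ import annotations

from .adult import RDATable, load_rda_table, score_adult
from .child import ChildScoringContext, population_median, score_child
from .io_model import BQIResult, Cohort
from .taxonomy import Taxonomy, load_taxonomy

__all__ = ["score_cohort", "check_taxonomy_coverage"]


def check_taxonomy_coverage(cohort: Cohort, taxonomy: Taxonomy) -> None:
    """Eagerly verify every breakfast food code classifies, before scoring."""
    unknown = sorted(
        {
            item.food_code
            for day in cohort.days.values()
            if day.breakfast() is not None
            for item in day.breakfast().items
            if item.food_code not in taxonomy.item_to_group
        }
    )
    if unknown:
        raise ValueError(f"food code(s) missing from taxonomy: {unknown[:10]}")


def score_cohort(
    cohort: Cohort,
    taxonomy: Taxonomy | None = None,
    rda_table: RDATable | None = None,
) -> tuple[dict[str, BQIResult], ChildScoringContext | None]:
    """Score every participant; returns (results, child context or None)."""
    taxonomy = taxonomy or load_taxonomy()
    check_taxonomy_coverage(cohort, taxonomy)
    results: dict[str, BQIResult] = {}
    if cohort.stream == "adult":
        rda_table = rda_table or load_rda_table()
        for pid, day in cohort.days.items():
            p = cohort.participants[pid]
            results[pid] = score_adult(day, taxonomy, rda_table, p.sex, p.age_years)
        return results, None
    context = population_median(cohort)
    for pid, day in cohort.days.items():
        results[pid] = score_child(day, taxonomy, context)
    return results, context
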