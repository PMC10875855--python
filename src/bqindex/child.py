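"""Child/adolescent Breakfast Quality Index: ten components, score 0-10.

The child variant scores presence of cereals and derivatives, dairy,
fruit/vegetables, and MUFA-rich added fats (olive/vegetable oil); limits the
energy from simple-sugar sources (added sugar, jam, honey) at breakfast to
< 5% of total daily energy; awards the MUFA:SFA point when the breakfast
ratio exceeds the cohort median (strictly); requires breakfast energy within
20-25% of daily energy and breakfast calcium within 200-300 mg; awards a
point for the absence of butter/margarine; and a final point when cereals,
fruit/vegetables and dairy appear in the same breakfast meal.

The MUFA:SFA criterion is population-relative, so scoring a cohort is a
two-pass operation: compute the cohort median of breakfast MUFA:SFA ratios
once (``population_median``), then score each child against it.
Categories: low 0-4, medium 5, high 6-10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .adult import KCAL_PER_G_SUGAR, ScoringError
from .io_model import BQIResult, Cohort, DietaryDay
from .taxonomy import Taxonomy, group_presence

__all__ = [
    "CHILD_COMPONENTS",
    "ChildScoringContext",
    "mufa_sfa_ratio",
    "population_median",
    "child_components",
    "score_child",
    "categorize_child",
]

CHILD_COMPONENTS = (
    "cereals",
    "fruit_veg",
    "dairy",
    "mufa_fats",
    "added_sugar",
    "mufa_sfa_ratio",
    "energy_share",
    "calcium",
    "no_butter",
    "combination",
)


@dataclass(frozen=True)
class ChildScoringContext:
    """Cohort-level state for the population-relative ratio criterion."""

    mufa_sfa_median: float

    def __post_init__(self) -> None:
        if math.isnan(self.mufa_sfa_median) or self.mufa_sfa_median < 0:
            raise ScoringError(f"invalid MUFA:SFA median {self.mufa_sfa_median!r}")


def mufa_sfa_ratio(day: DietaryDay, zero_over_zero: float = 0.0) -> float:
    """Breakfast MUFA (g) / breakfast SFA (g).

    Conventions for degenerate breakfasts: SFA = 0 with MUFA > 0 maps to
    +inf (above any finite median); MUFA = SFA = 0 maps to ``zero_over_zero``
    (default 0.0, never above a positive median).
    """
    bkf = day.breakfast()
    if bkf is None:
        raise ScoringError(f"participant {day.participant_id}: no breakfast occasion")
    bt = bkf.totals()
    if bt.sfa_g == 0:
        return math.inf if bt.mufa_g > 0 else zero_over_zero
    return bt.mufa_g / bt.sfa_g


def population_median(cohort: Cohort, zero_over_zero: float = 0.0) -> ChildScoringContext:
    """Median breakfast MUFA:SFA ratio over every child in the cohort.

    Even-n convention: mean of the two central order statistics (with +inf
    sentinels ordered above every finite ratio).
    """
    if len(cohort) == 0:
        raise ScoringError("cannot compute a population median on an empty cohort")
    ratios = sorted(mufa_sfa_ratio(day, zero_over_zero) for day in cohort.days.values())
    n = len(ratios)
    if n % 2 == 1:
        med = ratios[n // 2]
    else:
        a, b = ratios[n // 2 - 1], ratios[n // 2]
        med = a if a == b else (a + b) / 2.0  # keeps inf == inf well-defined
    return ChildScoringContext(mufa_sfa_median=med)


def child_components(
    day: DietaryDay,
    taxonomy: Taxonomy,
    context: ChildScoringContext,
    zero_over_zero: float = 0.0,
) -> dict[str, bool]:
    """Evaluate the ten child criteria for one recall day."""
    if context is None:
        raise ScoringError("child scoring requires a ChildScoringContext (cohort median)")
    bkf = day.breakfast()
    if bkf is None:
        raise ScoringError(f"participant {day.participant_id}: no breakfast occasion")
    daily = day.totals()
    if daily.energy_kcal <= 0:
        raise ScoringError(f"participant {day.participant_id}: daily energy is zero")
    bt = bkf.totals()
    present = group_presence(bkf, taxonomy)

    cereals = "cereals_derivatives" in present
    fruit_veg = "fruit_vegetables" in present
    dairy = "dairy" in present

    # Energy from simple-sugar-source items only (added sugar, jam, honey),
    # via their free-sugar content at 4 kcal/g.
    sugar_source_g = sum(
        item.nutrients.free_sugar_g
        for item in bkf.items
        if taxonomy.scoring_class_of(item.food_code) == "simple_sugar_sources"
    )
    added_sugar_ok = sugar_source_g * KCAL_PER_G_SUGAR < 0.05 * daily.energy_kcal

    share = bt.energy_kcal / daily.energy_kcal

    return {
        "cereals": cereals,
        "fruit_veg": fruit_veg,
        "dairy": dairy,
        "mufa_fats": "mufa_fats" in present,
        "added_sugar": added_sugar_ok,
        "mufa_sfa_ratio": mufa_sfa_ratio(day, zero_over_zero) > context.mufa_sfa_median,
        "energy_share": 0.20 <= share <= 0.25,
        "calcium": 200.0 <= bt.calcium_mg <= 300.0,
        "no_butter": "butter_margarine" not in present,
        "combination": cereals and fruit_veg and dairy,
    }


def categorize_child(score: int) -> str:
    """Category cut rule for children/adolescents: low 0-4, medium 5, high 6-10."""
    if not isinstance(score, (int,)) or not 0 <= score <= 10:
        raise ScoringError(f"child BQI score must be an integer in [0, 10], got {score!r}")
    if score <= 4:
        return "low"
    if score == 5:
        return "medium"
    return "high"


def score_child(
    day: DietaryDay,
    taxonomy: Taxonomy,
    context: ChildScoringContext,
    zero_over_zero: float = 0.0,
) -> BQIResult:
    """Score one child recall day against the cohort context."""
    components = child_components(day, taxonomy, context, zero_over_zero)
    score = sum(components.values())
    return BQIResult(components=components, score=score, category=categorize_child(score))
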