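"""Child/adolescent index: ratio conventions, cohort median, criteria."""

import math

import numpy as np
import pytest

from bqindex import (
    ChildScoringContext,
    categorize_child,
    child_components,
    mufa_sfa_ratio,
    population_median,
    score_child,
)
from bqindex.adult import ScoringError

from helpers import child_perfect_day, cohort_of, day, item


def _ratio_day(pid, mufa, sfa):
    bkf = [item("milk", 200, energy_kcal=300, mufa_g=mufa, sfa_g=sfa)]
    return day(pid, bkf, other_kcal=(600.0, 600.0))


@pytest.mark.parametrize(
    "mufa, sfa, expected",
    [(6, 3, 2.0), (2, 0, math.inf), (0, 0, 0.0), (0, 4, 0.0)],
)
def test_ratio_arithmetic_and_sentinels(mufa, sfa, expected):
    assert mufa_sfa_ratio(_ratio_day("p", mufa, sfa)) == expected


def test_zero_over_zero_convention_is_configurable():
    assert mufa_sfa_ratio(_ratio_day("p", 0, 0), zero_over_zero=0.5) == 0.5


@pytest.mark.parametrize(
    "ratios, expected",
    [((1, 2, 3), 2.0), ((1, 2, 3, 4), 2.5), ((2, 0, math.inf), 2.0)],
)
def test_population_median_conventions(ratios, expected):
    days = [_ratio_day(f"p{i}", r if math.isfinite(r) else 1.0, 1.0 if math.isfinite(r) else 0.0)
            for i, r in enumerate(ratios)]
    ctx = population_median(cohort_of(days, stream="child"))
    assert ctx.mufa_sfa_median == expected


def test_population_median_matches_sort_oracle():
    rng = np.random.default_rng(11)
    ratios = rng.lognormal(0, 0.8, size=505)
    days = [_ratio_day(f"p{i}", r, 1.0) for i, r in enumerate(ratios)]
    ctx = population_median(cohort_of(days, stream="child"))
    srt = np.sort(ratios)
    assert ctx.mufa_sfa_median == pytest.approx(srt[252], rel=1e-12)


def test_strictly_above_median_count_is_floor_n_over_2():
    """With tie-free ratios, exactly floor(n/2) children earn the point."""
    rng = np.random.default_rng(3)
    for n in (9, 10, 505):
        ratios = rng.permutation(np.linspace(0.1, 5.0, n) + rng.uniform(0, 1e-3, n))
        days = [_ratio_day(f"p{i}", r, 1.0) for i, r in enumerate(ratios)]
        cohort = cohort_of(days, stream="child")
        ctx = population_median(cohort)
        above = sum(mufa_sfa_ratio(d) > ctx.mufa_sfa_median for d in cohort.days.values())
        assert above == n // 2


def test_ties_at_the_median_score_zero(taxonomy):
    days = [_ratio_day("p0", 1, 1), _ratio_day("p1", 1, 1), _ratio_day("p2", 2, 1)]
    cohort = cohort_of(days, stream="child")
    ctx = population_median(cohort)
    assert ctx.mufa_sfa_median == 1.0
    comps = child_components(days[0], taxonomy, ctx)
    assert comps["mufa_sfa_ratio"] is False
    assert child_components(days[2], taxonomy, ctx)["mufa_sfa_ratio"] is True


def test_leave_one_out_median_stability():
    rng = np.random.default_rng(7)
    ratios = np.sort(rng.lognormal(0, 0.5, size=51))
    max_gap = np.diff(ratios).max()
    days = [_ratio_day(f"p{i}", r, 1.0) for i, r in enumerate(ratios)]
    full = population_median(cohort_of(days, stream="child")).mufa_sfa_median
    for drop in (0, 25, 50):
        reduced = [d for i, d in enumerate(days) if i != drop]
        med = population_median(cohort_of(reduced, stream="child")).mufa_sfa_median
        assert abs(med - full) <= max_gap + 1e-12


def test_empty_cohort_median_errors():
    with pytest.raises(ScoringError):
        population_median(cohort_of([], stream="child"))


def test_perfect_child_breakfast_scores_ten(taxonomy):
    ctx = ChildScoringContext(mufa_sfa_median=1.0)  # below the record's 2.2
    res = score_child(child_perfect_day(), taxonomy, ctx)
    assert all(res.components.values()), res.components
    assert res.score == 10
    assert res.category == "high"


def test_butter_only_breakfast_audit(taxonomy):
    """Butter-only breakfast: loses every presence point and the no-butter
    point; only the trivially-satisfied added-sugar limit remains."""
    d = day("p", [item("butter", 10, energy_kcal=74, sfa_g=5.1, mufa_g=2.1)], other_kcal=(900.0, 900.0))
    comps = child_components(d, taxonomy, ChildScoringContext(mufa_sfa_median=1.0))
    assert comps == {
        "cereals": False,
        "fruit_veg": False,
        "dairy": False,
        "mufa_fats": False,
        "added_sugar": True,
        "mufa_sfa_ratio": False,  # 2.1/5.1 = 0.41 < 1.0
        "energy_share": False,
        "calcium": False,
        "no_butter": False,
        "combination": False,
    }
    assert score_child(d, taxonomy, ChildScoringContext(1.0)).score <= 2


def test_added_sugar_counts_only_simple_sugar_sources(taxonomy):
    """Free sugar inside cereals does not count; jam/honey/sugar items do."""
    ctx = ChildScoringContext(mufa_sfa_median=1.0)
    sweet_cereal = day(
        "p",
        [item("biscuits", 60, energy_kcal=258, free_sugar_g=30)],
        other_kcal=(600.0, 600.0),
    )
    assert child_components(sweet_cereal, taxonomy, ctx)["added_sugar"] is True
    jammy = day(
        "p",
        [item("jam", 40, energy_kcal=112, free_sugar_g=26)],  # 104 kcal >= 5% of 1312
        other_kcal=(600.0, 600.0),
    )
    assert child_components(jammy, taxonomy, ctx)["added_sugar"] is False


def test_calcium_window_closed_at_both_ends(taxonomy):
    ctx = ChildScoringContext(mufa_sfa_median=1.0)
    for ca, inside in ((199.9, False), (200.0, True), (300.0, True), (300.1, False)):
        d = day("p", [item("milk", 200, energy_kcal=300, calcium_mg=ca)], other_kcal=(600.0, 600.0))
        assert child_components(d, taxonomy, ctx)["calcium"] is inside


@pytest.mark.parametrize(
    "score, category",
    [(0, "low"), (4, "low"), (5, "medium"), (6, "high"), (10, "high")],
)
def test_child_category_cut_points(score, category):
    assert categorize_child(score) == category


def test_child_category_rejects_out_of_range():
    with pytest.raises(ScoringError):
        categorize_child(11)
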