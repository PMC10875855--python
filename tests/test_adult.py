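"""Adult index: per-component criteria, category cuts, scale properties."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from bqindex import adult_components, categorize_adult, energy_share, eo_count, score_adult
from bqindex.adult import RDATable, ScoringError, load_rda_table

from helpers import adult_perfect_day, day, item


@pytest.mark.parametrize("n_other, expected", [(0, 1), (2, 3), (4, 5)])
def test_eo_count_counts_all_occasions(n_other, expected):
    d = day("p", [item("milk", 200, energy_kcal=92)], other_kcal=(400.0,) * n_other)
    assert eo_count(d) == expected


@pytest.mark.parametrize(
    "bkf_kcal, daily_rest, inside",
    [
        (400, 1600, True),    # 0.20
        (200, 1800, False),   # 0.10, below the window
        (300, 1700, True),    # exactly 15%: closed boundary
        (500, 1500, True),    # exactly 25%: closed boundary
        (520, 1480, False),   # 0.26, above
    ],
)
def test_energy_share_window_is_closed(taxonomy, rda, bkf_kcal, daily_rest, inside):
    d = day("p", [item("milk", 200, energy_kcal=bkf_kcal)], other_kcal=(daily_rest / 2, daily_rest / 2))
    assert energy_share(d) == pytest.approx(bkf_kcal / (bkf_kcal + daily_rest))
    comps = adult_components(d, taxonomy, rda, sex="woman", age_years=40)
    assert comps["energy_share"] is inside


def test_worked_example_hand_audit(taxonomy, rda):
    """EO=4, daily 2000 kcal; every inequality audited by hand.

    Breakfast: milk 200 g (92 kcal, Ca 240, SFA 3.7), biscuits 30 g
    (190 kcal, sugar 8 g, Na 120), apple 150 g (78 kcal, fibre 2 g, Na 30).
    Totals: 360 kcal (share 0.18), sugar 32 kcal < 50, Ca 240 >= 200,
    SFA 33.3 kcal < 50, fibre 2 <= 6.25 (fails), Na 150 < 500.
    """
    breakfast = [
        item("milk", 200, energy_kcal=92, calcium_mg=240, sfa_g=3.7),
        item("biscuits", 30, energy_kcal=190, free_sugar_g=8, sodium_mg=120),
        item("apple", 150, energy_kcal=78, fibre_g=2, sodium_mg=30),
    ]
    d = day("p", breakfast, other_kcal=(547.0, 547.0, 546.0))  # daily 2000
    comps = adult_components(d, taxonomy, rda, sex="woman", age_years=40)
    assert comps == {
        "cereals": True,
        "fruit_veg": True,
        "dairy": True,
        "combination": True,
        "energy_share": True,
        "free_sugar": True,
        "calcium": True,
        "sfa": True,
        "fibre": False,
        "sodium": True,
    }
    res = score_adult(d, taxonomy, rda, sex="woman", age_years=40)
    assert res.score == 9
    assert res.category == "high"


def test_zero_intake_breakfast_passes_less_than_criteria(taxonomy, rda):
    """A coffee-only breakfast: absence satisfies every '<' criterion."""
    d = day("p", [item("coffee", 40, energy_kcal=0.8)], other_kcal=(1000.0, 999.2))
    comps = adult_components(d, taxonomy, rda, sex="man", age_years=50)
    assert comps == {
        "cereals": False,
        "fruit_veg": False,
        "dairy": False,
        "combination": False,
        "energy_share": False,  # 0.0004, below 15%
        "free_sugar": True,
        "calcium": False,
        "sfa": True,
        "fibre": False,
        "sodium": True,
    }
    assert score_adult(d, taxonomy, rda, "man", 50).score == 3


def test_all_components_true_reaches_the_ceiling(taxonomy, rda):
    res = score_adult(adult_perfect_day(), taxonomy, rda, sex="woman", age_years=30)
    assert all(res.components.values())
    assert res.score == 10
    assert res.category == "high"


def test_combination_rule_any2_switch(taxonomy, rda):
    d = day("p", [item("milk", 200, energy_kcal=92), item("biscuits", 30, energy_kcal=130)])
    strict = adult_components(d, taxonomy, rda, "woman", 40)
    loose = adult_components(d, taxonomy, rda, "woman", 40, combination_rule="any2")
    assert strict["combination"] is False
    assert loose["combination"] is True


@pytest.mark.parametrize(
    "score, category",
    [(0, "low"), (3, "low"), (4, "medium"), (6, "medium"), (7, "high"), (10, "high")],
)
def test_category_cut_points(score, category):
    assert categorize_adult(score) == category


@pytest.mark.parametrize("bad", [-1, 11, 5.5])
def test_category_rejects_out_of_range(bad):
    with pytest.raises(ScoringError):
        categorize_adult(bad)


def test_rda_lookup_and_validation():
    table = load_rda_table()
    assert table.calcium_rda("woman", 45) == 1000
    assert table.calcium_rda("man", 70) == 1200
    assert table.life_stage("woman", 45) != table.life_stage("woman", 70)
    with pytest.raises(ScoringError, match="no RDA band"):
        table.calcium_rda("woman", 15)
    with pytest.raises(ScoringError, match="overlap"):
        RDATable(bands=(("woman", 20, 60, 1000), ("woman", 55, 120, 1200)))
    with pytest.raises(ScoringError, match="gap"):
        RDATable(bands=(("woman", 20, 40, 1000), ("woman", 60, 120, 1200)))
    with pytest.raises(ScoringError, match="> 0"):
        RDATable(bands=(("woman", 20, 120, 0),))


@given(
    sugar=st.floats(0, 60),
    sfa=st.floats(0, 30),
    fibre=st.floats(0, 40),
    sodium=st.floats(0, 3000),
    eo_pair=st.tuples(st.integers(1, 5), st.integers(1, 5)).filter(lambda t: t[0] < t[1]),
)
def test_eo_monotonicity_directions(sugar, sfa, fibre, sodium, eo_pair):
    """Holding intakes fixed, a larger EO count tightens the '<' criteria
    (true can only become false) and loosens the fibre '>' criterion."""
    from bqindex import load_taxonomy

    tax = load_taxonomy()
    rda = load_rda_table()
    comps = {}
    for eo in eo_pair:
        bkf = [
            item(
                "milk",
                200,
                energy_kcal=300,
                free_sugar_g=sugar,
                sfa_g=sfa,
                fibre_g=fibre,
                sodium_mg=sodium,
            )
        ]
        d = day("p", bkf, other_kcal=(1700.0 / eo,) * eo)  # eo other occasions
        comps[eo] = adult_components(d, tax, rda, "woman", 40)
    small, large = comps[eo_pair[0]], comps[eo_pair[1]]
    for name in ("free_sugar", "sfa", "sodium"):
        if large[name]:
            assert small[name]
    if small["fibre"]:
        assert large["fibre"]


def test_adding_zero_nutrient_qualifying_item_never_lowers_score(taxonomy, rda):
    base = day("p", [item("milk", 200, energy_kcal=300)], other_kcal=(850.0, 850.0))
    augmented = day(
        "p",
        [item("milk", 200, energy_kcal=300), item("vegetables", 50), item("biscuits", 20)],
        other_kcal=(850.0, 850.0),
    )
    s0 = score_adult(base, taxonomy, rda, "woman", 40).score
    s1 = score_adult(augmented, taxonomy, rda, "woman", 40).score
    assert s1 >= s0
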