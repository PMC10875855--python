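"""Builders for recall-day and cohort test objects."""

from __future__ import annotations

from bqindex import (
    Cohort,
    DietaryDay,
    EatingOccasion,
    FoodIntake,
    NutrientProfile,
    Participant,
)


def item(code: str, grams: float = 100.0, **nutrients: float) -> FoodIntake:
    return FoodIntake(food_code=code, grams=grams, nutrients=NutrientProfile(**nutrients))


def mixed_meal(kcal: float) -> FoodIntake:
    """Generic non-breakfast dish delivering ``kcal`` with bland nutrients."""
    return item(
        "mixed_meal",
        grams=kcal / 1.5,
        energy_kcal=kcal,
        free_sugar_g=kcal * 0.013,
        calcium_mg=kcal * 0.2,
        sfa_g=kcal * 0.01,
        mufa_g=kcal * 0.013,
        fibre_g=kcal * 0.01,
        sodium_mg=kcal * 2.3,
    )


def day(
    pid: str,
    breakfast_items: list[FoodIntake] | None,
    other_kcal: tuple[float, ...] = (500.0, 500.0, 500.0),
) -> DietaryDay:
    occasions = []
    if breakfast_items:
        occasions.append(EatingOccasion(label="breakfast", items=breakfast_items, time="07:30"))
    occasions += [
        EatingOccasion(label=f"meal_{i + 2}", items=[mixed_meal(k)]) for i, k in enumerate(other_kcal)
    ]
    return DietaryDay(participant_id=pid, occasions=occasions)


def adult_perfect_day(pid: str = "A1") -> DietaryDay:
    """EO=4, daily 2000 kcal, every adult criterion satisfied (hand-audited).

    Breakfast totals: 470 kcal (share 0.235), free sugar 4 g (16 kcal < 50),
    calcium 269 mg (>= 200), SFA 3.1 g (27.9 kcal < 50), fibre 11.1 g
    (> 6.25), sodium 332 mg (< 500); cereals + dairy + fruit all present.
    """
    breakfast = [
        item(
            "breakfast_cereals",
            80,
            energy_kcal=300,
            free_sugar_g=4,
            calcium_mg=20,
            sfa_g=0.8,
            mufa_g=1.2,
            fibre_g=7.5,
            sodium_mg=240,
        ),
        item("milk", 200, energy_kcal=92, calcium_mg=240, sfa_g=2.2, mufa_g=1.0, sodium_mg=90),
        item("apple", 150, energy_kcal=78, calcium_mg=9, sfa_g=0.1, mufa_g=0.1, fibre_g=3.6, sodium_mg=2),
    ]
    return day(pid, breakfast, other_kcal=(510.0, 510.0, 510.0))


def child_perfect_day(pid: str = "C1") -> DietaryDay:
    """EO=4, daily 1800 kcal, every child criterion satisfied (hand-audited).

    Breakfast: 403 kcal (share 0.224 in the 20-25% window), calcium 264 mg
    (in 200-300), no simple-sugar sources (0 < 5% of daily energy), olive
    oil present, no butter, MUFA:SFA = 8.8/4.0 = 2.2.
    """
    breakfast = [
        item(
            "bread",
            60,
            energy_kcal=168,
            free_sugar_g=1,
            calcium_mg=12,
            sfa_g=0.4,
            mufa_g=0.5,
            fibre_g=2.1,
            sodium_mg=300,
        ),
        item("milk", 200, energy_kcal=92, calcium_mg=240, sfa_g=2.2, mufa_g=1.0, sodium_mg=90),
        item("pear", 130, energy_kcal=55, calcium_mg=12, fibre_g=3.0, sodium_mg=1),
        item("olive_oil", 10, energy_kcal=88, sfa_g=1.4, mufa_g=7.3),
    ]
    return day(pid, breakfast, other_kcal=(466.0, 466.0, 465.0))


def cohort_of(
    days: list[DietaryDay],
    stream: str = "adult",
    ages: list[float] | None = None,
    sexes: list[str] | None = None,
    regular: list[str] | None = None,
) -> Cohort:
    default_age = 40.0 if stream == "adult" else 10.0
    participants = {}
    for i, d in enumerate(days):
        participants[d.participant_id] = Participant(
            participant_id=d.participant_id,
            age_years=ages[i] if ages else default_age,
            sex=sexes[i] if sexes else "woman",
            regular_breakfast_eater=regular[i] if regular else "yes",
        )
    return Cohort(participants=participants, days={d.participant_id: d for d in days}, stream=stream)
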