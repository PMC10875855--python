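"""Adult Breakfast Quality Index (BQI): ten components, score 0-10.

Components
----------
Three food-group presences at breakfast (cereals and derivatives,
fruit/vegetables, dairy), their same-meal combination, compliance of
breakfast energy with 15-25% of total daily energy, and five nutrient
criteria.  Four nutrient limits are daily limits divided by the number of
eating occasions (EO) in the recall day:

- free sugar: breakfast free-sugar energy < 10% of daily energy / EO
- saturated fat: breakfast SFA energy < 10% of daily energy / EO
- fibre: breakfast fibre > 25 g / EO
- sodium: breakfast sodium < 2000 mg / EO

and calcium: breakfast calcium >= 20% of the life-stage RDA.  One point per
component satisfied; no penalty components.  Inequalities are strict where
written strict; the energy window is closed at both ends.  The total is
categorised low (0-3), medium (4-6), high (7-10).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .io_model import BQIResult, DietaryDay
from .taxonomy import Taxonomy, group_presence

__all__ = [
    "ADULT_COMPONENTS",
    "KCAL_PER_G_SUGAR",
    "KCAL_PER_G_FAT",
    "RDATable",
    "load_rda_table",
    "eo_count",
    "energy_share",
    "adult_components",
    "score_adult",
    "categorize_adult",
]

ADULT_COMPONENTS = (
    "cereals",
    "fruit_veg",
    "dairy",
    "combination",
    "energy_share",
    "free_sugar",
    "calcium",
    "sfa",
    "fibre",
    "sodium",
)

# Atwater factors used to express gram intakes on the energy scale.
KCAL_PER_G_SUGAR = 4.0
KCAL_PER_G_FAT = 9.0


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class RDATable:
    """Calcium reference intakes keyed by (sex, age band).

    Bands must cover the adult age range for each sex without gaps or
    overlaps; the band an adult falls into is their life stage.
    """

    bands: tuple[tuple[str, float, float, float], ...]  # (sex, age_min, age_max, mg)

    def __post_init__(self) -> None:
        by_sex: dict[str, list[tuple[float, float, float]]] = {}
        for sex, lo, hi, mg in self.bands:
            if mg <= 0:
                raise ScoringError(f"calcium RDA must be > 0, got {mg} for {sex} {lo}-{hi}")
            if hi < lo:
                raise ScoringError(f"invalid age band {lo}-{hi}")
            by_sex.setdefault(sex, []).append((lo, hi, mg))
        for sex, bands in by_sex.items():
            bands.sort()
            for (lo1, hi1, _), (lo2, _hi2, _) in zip(bands, bands[1:]):
                if lo2 <= hi1:
                    raise ScoringError(f"overlapping RDA bands for {sex} near age {lo2}")
                if lo2 > hi1 + 1:
                    raise ScoringError(f"gap in RDA bands for {sex} between {hi1} and {lo2}")

    def life_stage(self, sex: str, age_years: float) -> str:
        for band_sex, lo, hi, _mg in self.bands:
            if band_sex == sex and lo <= age_years <= hi:
                return f"{band_sex}_{int(lo)}_{int(hi)}"
        raise ScoringError(f"no RDA band covers sex={sex!r}, age={age_years}")

    def calcium_rda(self, sex: str, age_years: float) -> float:
        for band_sex, lo, hi, mg in self.bands:
            if band_sex == sex and lo <= age_years <= hi:
                return mg
        raise ScoringError(f"no RDA band covers sex={sex!r}, age={age_years}")


def load_rda_table(config_path: str | Path | None = None) -> RDATable:
    """Load an RDA table from YAML; with no path, the packaged default."""
    if config_path is None:
        text = resources.files("bqindex.data").joinpath("rda_calcium.yaml").read_text()
    else:
        text = Path(config_path).read_text()
    raw = yaml.safe_load(text)
    bands = tuple(
        (str(b["sex"]), float(b["age_min"]), float(b["age_max"]), float(b["calcium_mg"]))
        for b in raw["bands"]
    )
    return RDATable(bands=bands)


def eo_count(day: DietaryDay) -> int:
    """Number of eating occasions in the recall day (breakfast included)."""
    n = day.eo_count()
    if n == 0:
        raise ScoringError("day has zero eating occasions")
    return n


def energy_share(day: DietaryDay) -> float:
    """Breakfast energy as a fraction of total daily energy."""
    bkf = day.breakfast()
    if bkf is None:
        raise ScoringError(f"participant {day.participant_id}: no breakfast occasion")
    daily = day.totals().energy_kcal
    if daily <= 0:
        raise ScoringError(f"participant {day.participant_id}: daily energy is zero")
    return bkf.totals().energy_kcal / daily


def adult_components(
    day: DietaryDay,
    taxonomy: Taxonomy,
    rda_table: RDATable,
    sex: str,
    age_years: float,
    combination_rule: str = "all3",
) -> dict[str, bool]:
    """Evaluate the ten adult criteria for one recall day.

    ``combination_rule`` is "all3" (cereals AND fruit/vegetables AND dairy in
    the same breakfast meal, the default) or "any2" (at least two of three).
    Note zero intake trivially satisfies every "less-than" criterion: a
    breakfast with no sugar passes the sugar limit.
    """
    bkf = day.breakfast()
    if bkf is None:
        raise ScoringError(f"participant {day.participant_id}: no breakfast occasion")
    eo = eo_count(day)
    daily = day.totals()
    if daily.energy_kcal <= 0:
        raise ScoringError(f"participant {day.participant_id}: daily energy is zero")
    bt = bkf.totals()
    present = group_presence(bkf, taxonomy)

    cereals = "cereals_derivatives" in present
    fruit_veg = "fruit_vegetables" in present
    dairy = "dairy" in present
    n_groups = cereals + fruit_veg + dairy
    if combination_rule == "all3":
        combination = n_groups == 3
    elif combination_rule == "any2":
        combination = n_groups >= 2
    else:
        raise ScoringError(f"unknown combination_rule {combination_rule!r}")

    share = bt.energy_kcal / daily.energy_kcal
    per_eo_energy_limit = 0.10 * daily.energy_kcal / eo

    return {
        "cereals": cereals,
        "fruit_veg": fruit_veg,
        "dairy": dairy,
        "combination": combination,
        "energy_share": 0.15 <= share <= 0.25,
        "free_sugar": bt.free_sugar_g * KCAL_PER_G_SUGAR < per_eo_energy_limit,
        "calcium": bt.calcium_mg >= 0.20 * rda_table.calcium_rda(sex, age_years),
        "sfa": bt.sfa_g * KCAL_PER_G_FAT < per_eo_energy_limit,
        "fibre": bt.fibre_g > 25.0 / eo,
        "sodium": bt.sodium_mg < 2000.0 / eo,
    }


def categorize_adult(score: int) -> str:
    """Category cut rule for adults: low 0-3, medium 4-6, high 7-10."""
    if not isinstance(score, (int,)) or not 0 <= score <= 10:
        raise ScoringError(f"adult BQI score must be an integer in [0, 10], got {score!r}")
    if score <= 3:
        return "low"
    if score <= 6:
        return "medium"
    return "high"


def score_adult(
    day: DietaryDay,
    taxonomy: Taxonomy,
    rda_table: RDATable,
    sex: str,
    age_years: float,
    combination_rule: str = "all3",
) -> BQIResult:
    """Score one adult recall day: components, 0-10 total, category."""
    components = adult_components(day, taxonomy, rda_table, sex, age_years, combination_rule)
    score = sum(components.values())
    return BQIResult(components=components, score=score, category=categorize_adult(score))
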