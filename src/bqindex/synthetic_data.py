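"""Synthetic nutrition-survey cohorts with known ground truth.

Generates participant covariate tables and long-format 24-h recall files
shaped like a telephone nutrition survey: each participant has 2-6 eating
occasions (truncated-Poisson count, mean 4), one of which is breakfast.
Breakfast composition is drawn food group by food group: a Bernoulli
consumption draw at the group's population prevalence (on the logit scale,
shifted by any planted covariate effects) followed by a lognormal portion
size; nutrients come from a fixture composition table.  Non-breakfast
occasions are filled with a generic mixed dish so that daily energy lands in
a realistic 1,400-3,200 kcal band.

Planted effects act mechanistically on food-choice logits, never directly on
the quality score, so recovering them through scoring + regression is a
genuine end-to-end test.  The fixture composition table is a synthetic
stand-in with reference-book-typical values; it is not survey ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln

from .correlates import derive_age_group

__all__ = [
    "FOOD_COMPOSITION",
    "SimulationParams",
    "default_adult_params",
    "default_child_params",
    "simulate_cohort",
    "simulate_with_skippers",
    "planted_truth",
    "write_simulation",
]

#: Synthetic food composition fixture: nutrient density per 100 g.
#: Order: energy_kcal, free_sugar_g, calcium_mg, sfa_g, mufa_g, fibre_g, sodium_mg.
_DENSITY_FIELDS = (
    "energy_kcal",
    "free_sugar_g",
    "calcium_mg",
    "sfa_g",
    "mufa_g",
    "fibre_g",
    "sodium_mg",
)

FOOD_COMPOSITION: dict[str, dict[str, float]] = {
    code: dict(zip(_DENSITY_FIELDS, vals))
    for code, vals in {
        "milk": (46, 0, 120, 1.1, 0.5, 0, 45),
        "coffee": (2, 0, 2, 0, 0, 0, 1),
        "tea": (1, 0, 0, 0, 0, 0, 1),
        "bread_substitutes": (280, 2, 20, 0.6, 0.8, 3.5, 500),
        "cakes_pies_biscuits": (430, 25, 30, 6, 5, 2.5, 300),
        "breakfast_cereals": (380, 20, 30, 1, 1.5, 7, 400),
        "other_cereals": (350, 1, 15, 0.5, 0.8, 5, 5),
        "fruit": (50, 0, 15, 0.1, 0.1, 2.2, 2),
        "nuts": (600, 1, 100, 5, 30, 7, 5),
        "vegetables": (25, 0, 40, 0.1, 0.1, 2.5, 10),
        "yogurt": (80, 10, 120, 1.8, 0.8, 0, 50),
        "cheese": (350, 0, 700, 17, 7, 0, 600),
        "other_milk_products": (100, 8, 110, 2, 1, 0, 60),
        "cocoa_drinks": (80, 8, 100, 1.5, 0.6, 0.5, 60),
        "fruit_juice": (45, 9, 10, 0, 0, 0.1, 3),
        "added_sugar": (392, 98, 0, 0, 0, 0, 0),
        "jam_honey": (280, 65, 10, 0, 0, 0.5, 15),
        "butter_margarine": (740, 0, 15, 51, 21, 0, 600),
        "olive_oil": (884, 0, 0, 14, 73, 0, 0),
        "vegetable_fat_oil": (884, 0, 0, 10, 60, 0, 0),
        "nut_spread": (540, 56, 110, 10, 20, 4, 40),
        "snacks": (480, 5, 20, 8, 10, 3, 700),
        "soft_drinks": (40, 10, 0, 0, 0, 0, 5),
        "cocoa_energy_drinks": (45, 9, 10, 0, 0, 0, 20),
        "meat_fish_eggs": (200, 0, 20, 4, 5, 0, 500),
        "vegetarian_vegan": (60, 3, 30, 0.3, 0.8, 1, 40),
        "water": (0, 0, 0, 0, 0, 0, 0),
        "mixed_meal": (150, 2, 30, 1.5, 2, 1.5, 350),
    }.items()
}


def validate_composition(table: dict[str, dict[str, float]] = FOOD_COMPOSITION) -> None:
    """Sanity-check the fixture: non-negative densities; energy consistent
    with the listed macronutrients to within 30%."""
    for code, d in table.items():
        for f, v in d.items():
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{code}: density {f} must be finite and >= 0")
        macro = 4 * d["free_sugar_g"] + 9 * (d["sfa_g"] + d["mufa_g"]) + 2 * d["fibre_g"]
        if macro > 1.3 * d["energy_kcal"] and macro > 1:
            raise ValueError(f"{code}: macronutrient energy {macro:.0f} exceeds 130% of energy")


validate_composition()

# (consumption probability, lognormal median grams, lognormal sigma)
ADULT_BREAKFAST_GROUPS: dict[str, tuple[float, float, float]] = {
    "milk": (0.617, 200, 0.25),
    "coffee": (0.72, 50, 0.30),
    "tea": (0.20, 200, 0.25),
    "bread_substitutes": (0.441, 50, 0.35),
    "cakes_pies_biscuits": (0.387, 60, 0.35),
    "breakfast_cereals": (0.05, 40, 0.30),
    "added_sugar": (0.567, 8, 0.35),
    "fruit": (0.067, 150, 0.30),
    "fruit_juice": (0.038, 150, 0.25),
    "yogurt": (0.081, 125, 0.20),
    "jam_honey": (0.087, 25, 0.35),
}

CHILD_BREAKFAST_GROUPS: dict[str, tuple[float, float, float]] = {
    "milk": (0.75, 220, 0.25),
    "cakes_pies_biscuits": (0.493, 60, 0.35),
    "bread_substitutes": (0.188, 50, 0.35),
    "breakfast_cereals": (0.097, 40, 0.30),
    "coffee": (0.188, 40, 0.30),
    "cocoa_energy_drinks": (0.168, 200, 0.25),
    "fruit_juice": (0.079, 150, 0.25),
    "fruit": (0.045, 140, 0.30),
    "added_sugar": (0.301, 8, 0.35),
    "jam_honey": (0.05, 25, 0.35),
    "yogurt": (0.081, 125, 0.20),
    "olive_oil": (0.028, 8, 0.30),
    "butter_margarine": (0.022, 10, 0.30),
}

ADULT_COVARIATE_FREQS: dict[str, dict[str, float]] = {
    "sex": {"woman": 0.546, "man": 0.454},
    "area": {"northern": 0.420, "central": 0.172, "southern": 0.408},
    "residence": {"rural": 0.136, "urban": 0.864},
    "education": {
        "up_to_elementary": 0.182,
        "lower_secondary": 0.255,
        "upper_secondary": 0.398,
        "postsecondary": 0.165,
    },
    "occupation": {
        "non_manual": 0.312,
        "manual": 0.168,
        "housewife": 0.108,
        "retired": 0.368,
        "student": 0.016,
        "unemployed": 0.028,
    },
    "marital_status": {"married": 0.752, "unmarried": 0.144, "separated_divorced": 0.031, "widowed": 0.073},
    "smoking": {"never": 0.623, "current": 0.138, "former": 0.220, "occasional": 0.019},
    "sport": {"no": 0.810, "yes": 0.190},
    "bmi_category": {"normal": 0.489, "overweight": 0.380, "obese": 0.131},
    "cvd": {"no": 0.966, "yes": 0.034},
    "cancer": {"no": 0.967, "yes": 0.033},
    "hypertension": {"no": 0.676, "yes": 0.324},
    "hyperlipidaemia": {"no": 0.782, "yes": 0.218},
    "diabetes": {"no": 0.922, "yes": 0.078},
    "self_rated_health": {"excellent": 0.158, "good": 0.647, "fair": 0.183, "poor": 0.012},
    "adverse_life_events": {"none": 0.891, "at_least_one": 0.109},
    "stress_home": {"never": 0.028, "sometimes": 0.554, "most_times": 0.382, "often_always": 0.036},
    "stress_work": {
        "never": 0.019,
        "sometimes": 0.196,
        "most_times": 0.271,
        "often": 0.042,
        "always": 0.019,
        "not_working": 0.453,
    },
    "financial_stress": {"little_none": 0.020, "moderate": 0.571, "high": 0.378, "non_responder": 0.031},
}

CHILD_COVARIATE_FREQS: dict[str, dict[str, float]] = {
    "sex": {"woman": 0.473, "man": 0.527},
    "area": {"northern": 0.212, "central": 0.087, "southern": 0.701},
    "residence": {"rural": 0.121, "urban": 0.879},
    "education": {"up_to_elementary": 0.356, "lower_upper_secondary": 0.644},
    "smoking": {"never": 0.887, "current": 0.113},
    "sport": {"no": 0.337, "yes": 0.663},
    "bmi_category": {"normal": 0.830, "overweight_obese": 0.170},
}

ADULT_AGE_BANDS = ((20, 40, 0.116), (41, 65, 0.546), (66, 97, 0.338))
CHILD_AGE_BANDS = ((5, 12, 0.267), (13, 19, 0.733))

# Planted covariate effects: additive shifts on group consumption logits.
ADULT_PLANTED_EFFECTS: dict[tuple[str, str], dict[str, float]] = {
    ("age_group", ">65"): {"fruit": 1.5},
    ("education", "postsecondary"): {"fruit": 1.5, "breakfast_cereals": 1.0},
    ("financial_stress", "high"): {"fruit": -1.5, "milk": -1.0},
}

CHILD_PLANTED_EFFECTS: dict[tuple[str, str], dict[str, float]] = {
    ("area", "central"): {"milk": -1.2, "fruit": -1.0},
    ("area", "southern"): {"milk": -0.8},
}

# Direction each group moves the quality score when consumed more often.
_GROUP_SCORE_DIRECTION = {"butter_margarine": -1.0}  # everything else: +1


@dataclass
class SimulationParams:
    """Study conditions for one simulated cohort."""

    n: int
    seed: int
    stream: str = "adult"
    breakfast_groups: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    covariate_freqs: dict[str, dict[str, float]] = field(default_factory=dict)
    age_bands: tuple[tuple[int, int, float], ...] = ADULT_AGE_BANDS
    planted_effects: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    eo_mean: float = 4.0
    eo_min: int = 2
    eo_max: int = 6
    daily_energy_mean: float = 2100.0
    daily_energy_sd: float = 350.0
    daily_energy_range: tuple[float, float] = (1400.0, 3200.0)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for g, (p, med, sig) in self.breakfast_groups.items():
            if not 0 <= p <= 1:
                raise ValueError(f"group {g}: probability {p} outside [0, 1]")
            if med <= 0 or sig < 0:
                raise ValueError(f"group {g}: invalid portion parameters")
            if g not in FOOD_COMPOSITION:
                raise ValueError(f"group {g}: no composition fixture entry")
        for var, freqs in self.covariate_freqs.items():
            tot = sum(freqs.values())
            if abs(tot - 1.0) > 1e-6:
                raise ValueError(f"covariate {var}: frequencies sum to {tot}, not 1")


def default_adult_params(n: int = 7673, seed: int = 0) -> SimulationParams:
    return SimulationParams(
        n=n,
        seed=seed,
        stream="adult",
        breakfast_groups=dict(ADULT_BREAKFAST_GROUPS),
        covariate_freqs={k: dict(v) for k, v in ADULT_COVARIATE_FREQS.items()},
        age_bands=ADULT_AGE_BANDS,
        planted_effects={k: dict(v) for k, v in ADULT_PLANTED_EFFECTS.items()},
    )


def default_child_params(n: int = 505, seed: int = 0) -> SimulationParams:
    return SimulationParams(
        n=n,
        seed=seed,
        stream="child",
        breakfast_groups=dict(CHILD_BREAKFAST_GROUPS),
        covariate_freqs={k: dict(v) for k, v in CHILD_COVARIATE_FREQS.items()},
        age_bands=CHILD_AGE_BANDS,
        planted_effects={k: dict(v) for k, v in CHILD_PLANTED_EFFECTS.items()},
        daily_energy_mean=1900.0,
        daily_energy_sd=300.0,
    )


def _truncated_poisson_pmf(mean: float, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
    """pmf of a Poisson truncated to [lo, hi] with the given truncated mean."""
    ks = np.arange(lo, hi + 1)

    def trunc_mean(lam: float) -> float:
        logp = ks * np.log(lam) - lam - gammaln(ks + 1)
        p = np.exp(logp - logp.max())
        p /= p.sum()
        return float((ks * p).sum())

    lam = brentq(lambda l: trunc_mean(l) - mean, 1e-3, 100.0)
    logp = ks * np.log(lam) - lam - gammaln(ks + 1)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return ks, p


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def simulate_cohort(params: SimulationParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort; returns (participants, recall) DataFrames.

    Fully deterministic under ``params.seed``.  All participants are regular
    breakfast eaters with a non-empty breakfast occasion, so the exclusion
    cascade retains everyone by default.  A participant whose Bernoulli
    draws select no food still gets a breakfast occasion holding a glass of
    water, keeping the recall structurally complete without perturbing the
    configured group prevalences.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    pids = np.array([f"{params.stream[0].upper()}{i:06d}" for i in range(n)])

    # --- covariates ---------------------------------------------------------
    band_p = np.array([b[2] for b in params.age_bands])
    band_idx = rng.choice(len(params.age_bands), p=band_p / band_p.sum(), size=n)
    lo = np.array([b[0] for b in params.age_bands])[band_idx]
    hi = np.array([b[1] for b in params.age_bands])[band_idx]
    age = rng.integers(lo, hi + 1)
    age_group = np.array([derive_age_group(a, params.stream) for a in age])

    cov: dict[str, np.ndarray] = {}
    for var, freqs in params.covariate_freqs.items():
        levels = list(freqs)
        p = np.array([freqs[lv] for lv in levels])
        cov[var] = rng.choice(levels, p=p / p.sum(), size=n)
    cov_with_derived = {**cov, "age_group": age_group}

    # --- breakfast composition ---------------------------------------------
    consumed: dict[str, np.ndarray] = {}
    grams: dict[str, np.ndarray] = {}
    for group, (prob, med, sig) in params.breakfast_groups.items():
        logit = np.full(n, _logit(min(max(prob, 1e-9), 1 - 1e-9)))
        for (var, level), shifts in params.planted_effects.items():
            if group in shifts and var in cov_with_derived:
                logit = logit + shifts[group] * (cov_with_derived[var] == level)
        p = 1.0 / (1.0 + np.exp(-logit))
        if prob >= 1.0:
            p = np.ones(n)
        elif prob <= 0.0:
            p = np.zeros(n)
        consumed[group] = rng.random(n) < p
        grams[group] = med * np.exp(sig * rng.standard_normal(n))

    any_food = np.zeros(n, dtype=bool)
    for m in consumed.values():
        any_food |= m
    water_only = ~any_food

    density = pd.DataFrame(FOOD_COMPOSITION).T  # code x nutrient, per 100 g
    bkf_energy = np.zeros(n)
    for group, mask in consumed.items():
        bkf_energy += mask * grams[group] * FOOD_COMPOSITION[group]["energy_kcal"] / 100.0

    # --- eating-occasion structure and rest-of-day energy -------------------
    ks, pmf = _truncated_poisson_pmf(params.eo_mean, params.eo_min, params.eo_max)
    eo = rng.choice(ks, p=pmf, size=n)
    target = np.clip(
        rng.normal(params.daily_energy_mean, params.daily_energy_sd, size=n),
        *params.daily_energy_range,
    )
    n_other = eo - 1
    other_energy = np.maximum(target - bkf_energy, 100.0 * n_other)
    max_other = params.eo_max - 1
    w = rng.gamma(4.0, size=(n, max_other))
    occ_mask = np.arange(max_other)[None, :] < n_other[:, None]
    w = w * occ_mask
    w = w / w.sum(axis=1, keepdims=True)
    meal_kcal = other_energy[:, None] * w
    meal_density = FOOD_COMPOSITION["mixed_meal"]["energy_kcal"] / 100.0
    meal_grams = meal_kcal / meal_density

    # --- assemble recall rows -----------------------------------------------
    blocks: list[pd.DataFrame] = []

    def _food_block(idx: np.ndarray, code: str, g: np.ndarray, label: str, time: str, order: int) -> pd.DataFrame:
        d = FOOD_COMPOSITION[code]
        block = pd.DataFrame(
            {
                "participant_id": pids[idx],
                "occasion_label": label,
                "occasion_time": time,
                "food_code": code,
                "grams": np.round(g, 2),
            }
        )
        for nut in _DENSITY_FIELDS:
            block[nut] = np.round(block["grams"] * d[nut] / 100.0, 4)
        block["_pid_idx"] = idx
        block["_occ_idx"] = order
        return block

    for order, (group, mask) in enumerate(consumed.items()):
        idx = np.flatnonzero(mask)
        if len(idx):
            blocks.append(_food_block(idx, group, grams[group][idx], "breakfast", "07:30", 0))
    idx = np.flatnonzero(water_only)
    if len(idx):
        blocks.append(_food_block(idx, "water", np.full(len(idx), 200.0), "breakfast", "07:30", 0))

    occ_times = ["10:30", "13:00", "16:30", "20:00", "22:00"]
    for j in range(max_other):
        idx = np.flatnonzero(occ_mask[:, j])
        if len(idx):
            blocks.append(
                _food_block(idx, "mixed_meal", meal_grams[idx, j], f"meal_{j + 2}", occ_times[j % len(occ_times)], j + 1)
            )

    recall = pd.concat(blocks, ignore_index=True)
    recall = recall.sort_values(["_pid_idx", "_occ_idx"], kind="stable").drop(
        columns=["_pid_idx", "_occ_idx"]
    )
    recall = recall.reset_index(drop=True)

    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "age_years": age,
            "sex": cov.get("sex", np.repeat("woman", n)),
            "regular_breakfast_eater": "yes",
            **{var: values for var, values in cov.items() if var != "sex"},
        }
    )
    return participants, recall


def simulate_with_skippers(
    params: SimulationParams, skip_rate: float, missing_rate: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort with planted exclusions for testing the selection cascade.

    A ``missing_rate`` fraction of participants get missing breakfast
    regularity; a disjoint ``skip_rate`` fraction are marked breakfast
    skippers and lose their breakfast occasion (their remaining occasions
    are untouched, so the recall stays parseable).
    """
    for name, rate in (("skip_rate", skip_rate), ("missing_rate", missing_rate)):
        if not 0 <= rate < 1:
            raise ValueError(f"{name} must be in [0, 1), got {rate}")
    if skip_rate + missing_rate >= 1:
        raise ValueError("skip_rate + missing_rate must be < 1")

    participants, recall = simulate_cohort(params)
    rng = np.random.default_rng(params.seed + 1_000_003)
    u = rng.random(len(participants))
    missing_mask = u < missing_rate
    skip_mask = (u >= missing_rate) & (u < missing_rate + skip_rate)

    participants = participants.copy()
    participants.loc[missing_mask, "regular_breakfast_eater"] = "missing"
    participants.loc[skip_mask, "regular_breakfast_eater"] = "no"

    skip_ids = set(participants.loc[skip_mask, "participant_id"])
    drop = recall["participant_id"].isin(skip_ids) & (recall["occasion_label"] == "breakfast")
    recall = recall[~drop].reset_index(drop=True)
    return participants, recall


def planted_truth(params: SimulationParams) -> list[dict]:
    """Machine-readable ledger of planted effects and their expected
    direction on the breakfast-quality score."""
    ledger = []
    for (var, level), shifts in params.planted_effects.items():
        net = sum(s * _GROUP_SCORE_DIRECTION.get(g, 1.0) for g, s in shifts.items())
        ledger.append(
            {
                "variable": var,
                "level": level,
                "direction": "+" if net > 0 else "-",
                "logit_shifts": dict(shifts),
            }
        )
    return ledger


def write_simulation(
    params: SimulationParams,
    outdir: str | Path,
    skip_rate: float = 0.0,
    missing_rate: float = 0.0,
) -> dict[str, Path]:
    """Write participants.csv, recall.csv and truth.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if skip_rate or missing_rate:
        participants, recall = simulate_with_skippers(params, skip_rate, missing_rate)
    else:
        participants, recall = simulate_cohort(params)
    paths = {
        "participants": outdir / "participants.csv",
        "recall": outdir / "recall.csv",
        "truth": outdir / "truth.json",
    }
    participants.to_csv(paths["participants"], index=False)
    recall.to_csv(paths["recall"], index=False)
    paths["truth"].write_text(json.dumps(planted_truth(params), indent=2))
    return paths
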