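"""Domain model and file I/O for single-day 24-h dietary recall data.

A recall day is a sequence of eating occasions (breakfast, other meals and
snacks); every occasion holds the foods consumed with their gram amounts and
the absolute nutrient contributions of the consumed portion.  The module also
implements the participant-selection cascade applied before breakfast-quality
scoring: drop participants with missing breakfast-regularity information,
then habitual breakfast skippers, then recall days without a usable
breakfast (no breakfast occasion or zero daily energy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "NUTRIENT_FIELDS",
    "RECALL_COLUMNS",
    "PARTICIPANT_COLUMNS",
    "RecallDataError",
    "SchemaError",
    "ReferentialError",
    "NutrientProfile",
    "FoodIntake",
    "EatingOccasion",
    "DietaryDay",
    "Participant",
    "Cohort",
    "BQIResult",
    "ExclusionReport",
    "read_cohort",
    "apply_exclusions",
    "write_scores",
    "read_scores",
]

#: Nutrient columns of the recall file, in canonical order.
NUTRIENT_FIELDS = (
    "energy_kcal",
    "free_sugar_g",
    "calcium_mg",
    "sfa_g",
    "mufa_g",
    "fibre_g",
    "sodium_mg",
)

RECALL_COLUMNS = ("participant_id", "occasion_label", "food_code", "grams") + NUTRIENT_FIELDS
PARTICIPANT_COLUMNS = ("participant_id", "age_years", "sex", "regular_breakfast_eater")

BREAKFAST_LABEL = "breakfast"


class RecallDataError(ValueError):
    """Base class for malformed recall / participant data."""


class SchemaError(RecallDataError):
    """A required column is missing or a cell cannot be parsed."""


class ReferentialError(RecallDataError):
    """Recall rows reference a participant absent from the covariate file."""


@dataclass(frozen=True)
class NutrientProfile:
    """Absolute nutrient content of a consumed portion (not per 100 g)."""

    energy_kcal: float = 0.0
    free_sugar_g: float = 0.0
    calcium_mg: float = 0.0
    sfa_g: float = 0.0
    mufa_g: float = 0.0
    fibre_g: float = 0.0
    sodium_mg: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise RecallDataError(
                    f"nutrient {f.name} must be finite and >= 0, got {v!r}"
                )

    def __add__(self, other: "NutrientProfile") -> "NutrientProfile":
        return NutrientProfile(
            **{f.name: getattr(self, f.name) + getattr(other, f.name) for f in fields(self)}
        )

    @classmethod
    def zero(cls) -> "NutrientProfile":
        return cls()


@dataclass(frozen=True)
class FoodIntake:
    """One food or beverage consumed within an eating occasion."""

    food_code: str
    grams: float
    nutrients: NutrientProfile

    def __post_init__(self) -> None:
        if not self.food_code:
            raise RecallDataError("food_code must be non-empty")
        if not math.isfinite(self.grams) or self.grams <= 0:
            raise RecallDataError(f"grams must be > 0, got {self.grams!r}")


@dataclass
class EatingOccasion:
    """A distinct meal or snack event (EO) within the recall day."""

    label: str
    items: list[FoodIntake]
    time: str | None = None

    def __post_init__(self) -> None:
        if not self.items:
            raise RecallDataError(f"eating occasion {self.label!r} has no items")

    @property
    def is_breakfast(self) -> bool:
        return self.label.strip().lower() == BREAKFAST_LABEL

    def totals(self) -> NutrientProfile:
        total = NutrientProfile.zero()
        for item in self.items:
            total = total + item.nutrients
        return total

    def total_grams(self) -> float:
        return sum(item.grams for item in self.items)


@dataclass
class DietaryDay:
    """A participant's full recall day: ordered eating occasions.

    At most one occasion may carry the breakfast label; two labelled
    breakfasts is a data error (occasion-normalised thresholds assume
    distinct occasions), never a merge.
    """

    participant_id: str
    occasions: list[EatingOccasion]

    def __post_init__(self) -> None:
        if not self.occasions:
            raise RecallDataError(f"participant {self.participant_id}: day has no occasions")
        n_breakfast = sum(occ.is_breakfast for occ in self.occasions)
        if n_breakfast > 1:
            raise RecallDataError(
                f"participant {self.participant_id}: {n_breakfast} breakfast occasions"
            )

    def breakfast(self) -> EatingOccasion | None:
        for occ in self.occasions:
            if occ.is_breakfast:
                return occ
        return None

    def eo_count(self) -> int:
        return len(self.occasions)

    def totals(self) -> NutrientProfile:
        total = NutrientProfile.zero()
        for occ in self.occasions:
            total = total + occ.totals()
        return total


@dataclass
class Participant:
    participant_id: str
    age_years: float
    sex: str  # "woman" | "man"
    regular_breakfast_eater: str  # "yes" | "no" | "missing"
    covariates: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_years < 4:
            raise RecallDataError(
                f"participant {self.participant_id}: age {self.age_years} below survey minimum (4 y)"
            )
        if self.regular_breakfast_eater not in ("yes", "no", "missing"):
            raise RecallDataError(
                f"participant {self.participant_id}: regular_breakfast_eater must be "
                f"yes/no/missing, got {self.regular_breakfast_eater!r}"
            )


@dataclass
class Cohort:
    """Participants plus their recall days; the unit of scoring and analysis."""

    participants: dict[str, Participant]
    days: dict[str, DietaryDay]
    stream: str  # "adult" | "child"

    def __post_init__(self) -> None:
        if self.stream not in ("adult", "child"):
            raise ValueError(f"stream must be 'adult' or 'child', got {self.stream!r}")
        missing = set(self.participants) - set(self.days)
        if missing:
            raise RecallDataError(
                f"participants without a recall day: {sorted(missing)[:5]}"
            )
        extra = set(self.days) - set(self.participants)
        if extra:
            raise ReferentialError(
                f"recall days for unknown participants: {sorted(extra)[:5]}"
            )
        bad_age = [
            p.participant_id
            for p in self.participants.values()
            if (self.stream == "adult" and p.age_years < 20)
            or (self.stream == "child" and not (5 <= p.age_years <= 19))
        ]
        if bad_age:
            raise RecallDataError(
                f"ages outside the {self.stream} stream range: {sorted(bad_age)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.participants)

    def ids(self) -> list[str]:
        return list(self.participants)


@dataclass(frozen=True)
class BQIResult:
    """Per-participant breakfast-quality score.

    ``components`` is an ordered mapping of the ten named criteria to their
    booleans; the total is their count and the category follows the
    stream-specific cut rule (computed by the scoring modules).
    """

    components: Mapping[str, bool]
    score: int
    category: str

    def __post_init__(self) -> None:
        if len(self.components) != 10:
            raise ValueError(f"expected 10 components, got {len(self.components)}")
        popcount = sum(bool(v) for v in self.components.values())
        if self.score != popcount:
            raise ValueError(f"score {self.score} != number of true components {popcount}")
        if self.category not in ("low", "medium", "high"):
            raise ValueError(f"unknown category {self.category!r}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file is missing required column(s): {missing}")


def _coerce_numeric(df: pd.DataFrame, cols: Iterable[str], what: str) -> pd.DataFrame:
    df = df.copy()
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        nan = df.index[df[col].isna()].tolist()
        if bad or nan:
            rows = sorted(bad + nan)[:10]
            raise SchemaError(f"{what}: unparseable or missing numeric {col!r} at rows {rows}")
        df[col] = coerced
    return df


def read_cohort(recall_csv: str | Path, participant_csv: str | Path, stream: str) -> Cohort:
    """Read long-format recall and participant covariate files into a Cohort.

    Parsing is header-driven (column order is irrelevant); occasion grouping
    preserves file order within each (participant, occasion label) block.
    """
    recall = pd.read_csv(recall_csv, dtype={"participant_id": str}, comment="#")
    part = pd.read_csv(participant_csv, dtype={"participant_id": str}, comment="#")

    _require_columns(recall, RECALL_COLUMNS, "recall")
    _require_columns(part, PARTICIPANT_COLUMNS, "participant")

    recall = _coerce_numeric(recall, ("grams",) + NUTRIENT_FIELDS, "recall")
    bad_grams = recall.index[recall["grams"] <= 0].tolist()
    if bad_grams:
        raise RecallDataError(f"recall: grams must be > 0 at rows {bad_grams[:10]}")
    part = _coerce_numeric(part, ["age_years"], "participant")

    dup = part["participant_id"][part["participant_id"].duplicated()].tolist()
    if dup:
        raise RecallDataError(f"participant file: duplicate participant_id {dup[:5]}")

    known = set(part["participant_id"])
    orphans = sorted(set(recall["participant_id"]) - known)
    if orphans:
        raise ReferentialError(
            f"recall rows reference participants missing from covariate file: {orphans[:5]}"
        )

    covariate_cols = [c for c in part.columns if c not in PARTICIPANT_COLUMNS]
    participants: dict[str, Participant] = {}
    for row in part.itertuples(index=False):
        rec = row._asdict()
        reg = rec["regular_breakfast_eater"]
        if reg is None or (isinstance(reg, float) and math.isnan(reg)) or str(reg).strip() == "":
            reg = "missing"
        participants[rec["participant_id"]] = Participant(
            participant_id=rec["participant_id"],
            age_years=float(rec["age_years"]),
            sex=str(rec["sex"]),
            regular_breakfast_eater=str(reg),
            covariates={c: "" if pd.isna(rec[c]) else str(rec[c]) for c in covariate_cols},
        )

    has_time = "occasion_time" in recall.columns
    days: dict[str, DietaryDay] = {}
    for pid, pgroup in recall.groupby("participant_id", sort=False):
        occasions = []
        for label, ogroup in pgroup.groupby("occasion_label", sort=False):
            items = [
                FoodIntake(
                    food_code=str(r.food_code),
                    grams=float(r.grams),
                    nutrients=NutrientProfile(
                        **{n: float(getattr(r, n)) for n in NUTRIENT_FIELDS}
                    ),
                )
                for r in ogroup.itertuples(index=False)
            ]
            time = None
            if has_time:
                t = ogroup["occasion_time"].iloc[0]
                time = None if pd.isna(t) else str(t)
            occasions.append(EatingOccasion(label=str(label), items=items, time=time))
        days[str(pid)] = DietaryDay(participant_id=str(pid), occasions=occasions)

    return Cohort(participants=participants, days=days, stream=stream)


# ---------------------------------------------------------------------------
# Exclusion cascade
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExclusionReport:
    """Counts of participants dropped at each step, in application order."""

    input_n: int
    missing_regularity: int
    skipper: int
    no_breakfast_or_incomplete: int
    retained: int

    def as_dict(self) -> dict[str, int]:
        return {
            "input_n": self.input_n,
            "missing_regularity": self.missing_regularity,
            "skipper": self.skipper,
            "no_breakfast_or_incomplete": self.no_breakfast_or_incomplete,
            "retained": self.retained,
        }


def _diet_complete(day: DietaryDay) -> bool:
    """Breakfast occasion present and positive daily energy.

    Item-level nutrient completeness is already guaranteed by parsing (rows
    with missing nutrient cells are rejected at read time).
    """
    return day.breakfast() is not None and day.totals().energy_kcal > 0


def apply_exclusions(cohort: Cohort) -> tuple[Cohort, ExclusionReport]:
    """Apply the pre-scoring selection cascade.

    Order is fixed: missing breakfast-regularity -> breakfast skipper ->
    no breakfast occasion / incomplete dietary data.  A participant matching
    several reasons is counted once, under the first.  Idempotent.
    """
    missing = skipper = incomplete = 0
    keep: list[str] = []
    for pid, p in cohort.participants.items():
        if p.regular_breakfast_eater == "missing":
            missing += 1
        elif p.regular_breakfast_eater == "no":
            skipper += 1
        elif not _diet_complete(cohort.days[pid]):
            incomplete += 1
        else:
            keep.append(pid)

    filtered = Cohort(
        participants={pid: cohort.participants[pid] for pid in keep},
        days={pid: cohort.days[pid] for pid in keep},
        stream=cohort.stream,
    )
    report = ExclusionReport(
        input_n=len(cohort),
        missing_regularity=missing,
        skipper=skipper,
        no_breakfast_or_incomplete=incomplete,
        retained=len(keep),
    )
    return filtered, report


# ---------------------------------------------------------------------------
# Score file round-trip
# ---------------------------------------------------------------------------


def write_scores(results: Mapping[str, BQIResult], path: str | Path) -> None:
    """Write participant scores as CSV (component booleans as 0/1)."""
    rows = []
    component_names: list[str] | None = None
    for pid, res in results.items():
        if component_names is None:
            component_names = list(res.components)
        row = {"participant_id": pid}
        row.update({name: int(res.components[name]) for name in component_names})
        row["score"] = res.score
        row["category"] = res.category
        rows.append(row)
    if component_names is None:
        # Empty cohort: emit a header-only file with the canonical adult order.
        from .adult import ADULT_COMPONENTS

        component_names = list(ADULT_COMPONENTS)
    columns = ["participant_id", *component_names, "score", "category"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_scores(path: str | Path) -> dict[str, BQIResult]:
    """Read a scores CSV back into BQIResult objects (exact round-trip)."""
    df = pd.read_csv(path, dtype={"participant_id": str}, comment="#")
    component_names = [c for c in df.columns if c not in ("participant_id", "score", "category")]
    out: dict[str, BQIResult] = {}
    for r in df.itertuples(index=False):
        rec = r._asdict()
        out[rec["participant_id"]] = BQIResult(
            components={name: bool(rec[name]) for name in component_names},
            score=int(rec["score"]),
            category=str(rec["category"]),
        )
    return out
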