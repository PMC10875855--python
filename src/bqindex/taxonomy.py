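"""Food taxonomy: food codes -> reporting groups -> scoring classes.

The breakfast-quality indices never look at individual foods; they ask
whether a *scoring class* (cereals and derivatives, fruit/vegetables, dairy,
MUFA-rich fats, butter/margarine, simple-sugar sources) is present at the
breakfast occasion, and descriptive outputs aggregate gram amounts by
*reporting group* (milk, coffee, tea, ...).  The mapping is config-driven; a
packaged default ships with the library.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .io_model import Cohort, EatingOccasion

__all__ = [
    "SCORING_CLASSES",
    "TaxonomyError",
    "Taxonomy",
    "load_taxonomy",
    "group_presence",
    "group_grams",
]

#: Valid scoring classes.  "other" is scoring-neutral: groups in it never
#: contribute to any index criterion.
SCORING_CLASSES = frozenset(
    {
        "cereals_derivatives",
        "fruit_vegetables",
        "dairy",
        "mufa_fats",
        "butter_margarine",
        "simple_sugar_sources",
        "other",
    }
)

NEUTRAL_CLASS = "other"


class TaxonomyError(ValueError):
    pass


@dataclass(frozen=True)
class Taxonomy:
    item_to_group: dict[str, str]
    group_to_class: dict[str, str]

    def __post_init__(self) -> None:
        unknown = sorted(set(self.group_to_class.values()) - SCORING_CLASSES)
        if unknown:
            raise TaxonomyError(f"unknown scoring class name(s): {unknown}")
        orphan = sorted(set(self.item_to_group.values()) - set(self.group_to_class))
        if orphan:
            raise TaxonomyError(f"reporting group(s) without a scoring class: {orphan}")

    def group_of(self, food_code: str) -> str:
        try:
            return self.item_to_group[food_code]
        except KeyError:
            raise TaxonomyError(f"food code {food_code!r} is not in the taxonomy") from None

    def scoring_class_of(self, food_code: str) -> str:
        return self.group_to_class[self.group_of(food_code)]

    def groups(self) -> list[str]:
        return list(self.group_to_class)


def load_taxonomy(config_path: str | Path | None = None) -> Taxonomy:
    """Load a taxonomy from YAML; with no path, load the packaged default.

    Schema: a top-level ``groups`` mapping of reporting group ->
    ``{scoring_class: <name>, items: [food codes]}``.  A food code listed
    under two groups is a duplicate error.
    """
    if config_path is None:
        text = resources.files("bqindex.data").joinpath("taxonomy.yaml").read_text()
    else:
        text = Path(config_path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "groups" not in raw:
        raise TaxonomyError("taxonomy config must have a top-level 'groups' mapping")

    item_to_group: dict[str, str] = {}
    group_to_class: dict[str, str] = {}
    duplicates: list[str] = []
    for group, entry in raw["groups"].items():
        if not isinstance(entry, dict) or "scoring_class" not in entry or "items" not in entry:
            raise TaxonomyError(f"group {group!r} needs 'scoring_class' and 'items'")
        group_to_class[str(group)] = str(entry["scoring_class"])
        for code in entry["items"]:
            code = str(code)
            if code in item_to_group:
                duplicates.append(code)
            item_to_group[code] = str(group)
    if duplicates:
        raise TaxonomyError(f"food code(s) mapped to more than one group: {sorted(set(duplicates))}")
    return Taxonomy(item_to_group=item_to_group, group_to_class=group_to_class)


def group_presence(occasion: EatingOccasion, taxonomy: Taxonomy) -> set[str]:
    """Scoring classes present in an occasion.

    Presence depends on intake, not amount: a class is present iff at least
    one of its items was consumed (grams > 0 is guaranteed by the data
    model).  The neutral class "other" is never reported, so e.g. a
    coffee-only breakfast yields the empty set.
    """
    present = {taxonomy.scoring_class_of(item.food_code) for item in occasion.items}
    present.discard(NEUTRAL_CLASS)
    return present


def group_grams(cohort: Cohort, taxonomy: Taxonomy) -> pd.Series:
    """Total grams consumed at breakfast per reporting group, cohort-wide.

    Mass is conserved: the series sums to the total breakfast grams of the
    cohort.  Raises if any breakfast item is missing from the taxonomy.
    """
    totals: dict[str, float] = {}
    for day in cohort.days.values():
        bkf = day.breakfast()
        if bkf is None:
            continue
        for item in bkf.items:
            group = taxonomy.group_of(item.food_code)
            totals[group] = totals.get(group, 0.0) + item.grams
    return pd.Series(totals, dtype=float).sort_values(ascending=False)
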