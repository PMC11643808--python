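"""MIDUS Healthy Eating Index (MIDUS-HEI) scoring.

The MIDUS-HEI is a 10-component diet-quality index built from the MIDUS
food-intake questionnaire.  Five components reward healthy foods
(fruits/vegetables, whole grains, oily fish, lean meat, non-meat protein),
three penalise unhealthy foods (sugared beverages, high-fat meat, fast food),
and two are non-linear (fermented dairy, alcohol).  Each component scores
0 / 0.5 / 1 against its recommended-intake bands; fruits-and-vegetables is the
one double-weight component (0 / 0.5 / 1 / 2, a single questionnaire item
covering both food groups), so totals range from 0 (very unhealthy diet) to 11
(very healthy diet).

Band edges are printed as integer serving counts; real-valued intakes are
floored to whole servings before band lookup for the count-style items, while
items whose bands are genuine real intervals (oily fish, fast food, fermented
dairy) are compared directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "COMPONENTS",
    "DietResponse",
    "HEIScore",
    "UnscorableComponent",
    "score_component",
    "score_hei",
    "score_hei_table",
]

#: Component identifiers in canonical (questionnaire) order.
COMPONENTS = (
    "veg_fruit",
    "whole_grains",
    "oily_fish",
    "lean_meat",
    "nonmeat_protein",
    "sugared_bev",
    "high_fat_meat",
    "fast_food",
    "fermented_dairy",
    "alcohol",
)

#: Components whose score never decreases with intake.
DIRECT_COMPONENTS = ("veg_fruit", "whole_grains", "oily_fish", "lean_meat", "nonmeat_protein")
#: Components whose score never increases with intake.
INVERSE_COMPONENTS = ("sugared_bev", "high_fat_meat", "fast_food")

MAX_TOTAL = 11.0


class UnscorableComponent(ValueError):
    """A component cannot be scored, typically because of a missing response."""

    def __init__(self, component: str, reason: str = "missing response"):
        self.component = component
        self.reason = reason
        super().__init__(f"component {component!r} unscorable: {reason}")


@dataclass
class DietResponse:
    """One subject's answers to the ten food-component questions.

    Consumption fields are servings per day or per week as indicated by the
    suffix; ``alcohol_days_per_week``/``alcohol_drinks_per_day`` jointly encode
    drinking frequency and quantity.  ``None``/NaN marks a missing answer.
    """

    veg_fruit_per_day: Optional[float] = None
    whole_grains_per_day: Optional[float] = None
    oily_fish_per_week: Optional[float] = None
    lean_meat_per_week: Optional[float] = None
    nonmeat_protein_per_week: Optional[float] = None
    sugared_bev_per_day: Optional[float] = None
    high_fat_meat_per_week: Optional[float] = None
    fast_food_per_week: Optional[float] = None
    fermented_dairy_per_day: Optional[float] = None
    alcohol_days_per_week: Optional[float] = None
    alcohol_drinks_per_day: Optional[float] = None
    sex: Optional[str] = None  # "male" | "female"; required for the alcohol limit

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "sex" or v is None:
                continue
            if isinstance(v, float) and math.isnan(v):
                setattr(self, f.name, None)
            elif v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")


@dataclass
class HEIScore:
    """Component scores plus their total for one subject."""

    component_scores: dict
    total: float


def _require(value, component: str):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise UnscorableComponent(component)
    return float(value)


def score_component(component: str, response: DietResponse) -> float:
    """Score one MIDUS-HEI component for one subject.

    Returns 0, 0.5 or 1 (0/0.5/1/2 for ``veg_fruit``).  Raises
    :class:`UnscorableComponent` when a needed answer is missing.
    """
    if component == "veg_fruit":
        x = math.floor(_require(response.veg_fruit_per_day, component))
        if x >= 5:
            return 2.0
        if x >= 3:
            return 1.0
        if x >= 1:
            return 0.5
        return 0.0

    if component == "whole_grains":
        x = math.floor(_require(response.whole_grains_per_day, component))
        if x >= 3:
            return 1.0
        if x >= 1:
            return 0.5
        return 0.0

    if component == "oily_fish":
        x = _require(response.oily_fish_per_week, component)
        if x >= 1:
            return 1.0
        if x > 0:
            return 0.5
        return 0.0

    if component == "lean_meat":
        # printed bands overlap at 0 ("None" minimal vs "0-2" intermediate);
        # resolved as: exactly 0 -> 0, (0, 2] -> 0.5, >= 3 -> 1
        x = _require(response.lean_meat_per_week, component)
        if x == 0:
            return 0.0
        if math.floor(x) >= 3:
            return 1.0
        return 0.5

    if component == "nonmeat_protein":
        x = _require(response.nonmeat_protein_per_week, component)
        if math.floor(x) >= 3:
            return 1.0
        if x >= 1:
            return 0.5
        return 0.0

    if component == "sugared_bev":
        x = math.floor(_require(response.sugared_bev_per_day, component))
        if x >= 4:
            return 0.0
        if x >= 1:
            return 0.5
        return 1.0

    if component == "high_fat_meat":
        x = math.floor(_require(response.high_fat_meat_per_week, component))
        if x >= 3:
            return 0.0
        if x >= 1:
            return 0.5
        return 1.0

    if component == "fast_food":
        x = _require(response.fast_food_per_week, component)
        if x >= 1:
            return 0.0
        if x > 0:
            return 0.5
        return 1.0

    if component == "fermented_dairy":
        x = _require(response.fermented_dairy_per_day, component)
        if 2 <= x < 4:
            return 1.0
        if 1 <= x < 2 or 4 <= x < 5:
            return 0.5
        return 0.0

    if component == "alcohol":
        freq = _require(response.alcohol_days_per_week, component)
        qty = _require(response.alcohol_drinks_per_day, component)
        if response.sex not in ("male", "female"):
            raise UnscorableComponent(component, "sex required for the quantity limit")
        if freq == 0 or qty == 0:  # nondrinker
            return 0.0
        limit = 2.0 if response.sex == "male" else 1.0
        if qty > limit:  # over-limit drinking
            return 0.0
        if freq >= 3:
            return 1.0
        return 0.5

    raise KeyError(f"unknown component {component!r}")


def score_hei(response: DietResponse) -> HEIScore:
    """Score all ten components and their total for one subject.

    Raises :class:`UnscorableComponent` if any component cannot be scored;
    callers exclude such subjects from index-dependent analyses.
    """
    scores = {c: score_component(c, response) for c in COMPONENTS}
    total = float(sum(scores.values()))
    assert 0.0 <= total <= MAX_TOTAL
    return HEIScore(component_scores=scores, total=total)


# column names expected in a diet table (one row per subject)
DIET_COLUMNS = [f.name for f in fields(DietResponse)]


def score_hei_table(diet: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a diet table; returns ``(scores, exclusions)``.

    ``diet`` must contain the :class:`DietResponse` columns (extra columns are
    ignored) and is indexed by subject.  ``scores`` holds one column per
    component plus ``hei_total`` for scorable subjects; ``exclusions`` lists
    excluded subjects with a reason (mirroring complete-case handling of the
    questionnaire).
    """
    missing = [c for c in DIET_COLUMNS if c not in diet.columns]
    if missing:
        raise KeyError(f"diet table missing columns: {missing}")
    rows, excl = {}, []
    for sid, row in diet.iterrows():
        resp = DietResponse(**{c: row[c] for c in DIET_COLUMNS})
        try:
            hs = score_hei(resp)
        except UnscorableComponent as e:
            excl.append({"subject_id": sid, "reason": f"{e.component}: {e.reason}"})
            continue
        rows[sid] = {**hs.component_scores, "hei_total": hs.total}
    scores = pd.DataFrame.from_dict(rows, orient="index")
    scores.index.name = diet.index.name or "subject_id"
    if scores.empty:
        scores = pd.DataFrame(columns=[*COMPONENTS, "hei_total"])
    exclusions = pd.DataFrame(excl, columns=["subject_id", "reason"])
    return scores, exclusions
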