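"""Healthy-eating-index scoring: band lookups, totals, and exclusions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dietsig.hei import (COMPONENTS, DIRECT_COMPONENTS, INVERSE_COMPONENTS,
                         DietResponse, UnscorableComponent, score_component,
                         score_hei, score_hei_table)

MAXIMAL = dict(veg_fruit_per_day=6, whole_grains_per_day=3, oily_fish_per_week=1,
               lean_meat_per_week=3, nonmeat_protein_per_week=3, sugared_bev_per_day=0,
               high_fat_meat_per_week=0, fast_food_per_week=0, fermented_dairy_per_day=2,
               alcohol_days_per_week=3, alcohol_drinks_per_day=1, sex="female")

MINIMAL = dict(veg_fruit_per_day=0, whole_grains_per_day=0, oily_fish_per_week=0,
               lean_meat_per_week=0, nonmeat_protein_per_week=0, sugared_bev_per_day=4,
               high_fat_meat_per_week=3, fast_food_per_week=1, fermented_dairy_per_day=0,
               alcohol_days_per_week=0, alcohol_drinks_per_day=0, sex="male")


def resp(**kw):
    base = dict(MAXIMAL)
    base.update(kw)
    return DietResponse(**base)


@pytest.mark.parametrize("component,fields,expected", [
    # fruits & vegetables: the only double-score component
    ("veg_fruit", {"veg_fruit_per_day": 5}, 2),
    ("veg_fruit", {"veg_fruit_per_day": 0}, 0),
    ("veg_fruit", {"veg_fruit_per_day": 1}, 0.5),
    ("veg_fruit", {"veg_fruit_per_day": 2.5}, 0.5),  # floored to 2 -> "1-2" band
    ("veg_fruit", {"veg_fruit_per_day": 3}, 1),
    ("veg_fruit", {"veg_fruit_per_day": 4}, 1),
    ("whole_grains", {"whole_grains_per_day": 1}, 0.5),
    ("whole_grains", {"whole_grains_per_day": 3}, 1),
    ("whole_grains", {"whole_grains_per_day": 0}, 0),
    ("oily_fish", {"oily_fish_per_week": 1}, 1),
    ("oily_fish", {"oily_fish_per_week": 0.5}, 0.5),
    ("oily_fish", {"oily_fish_per_week": 0}, 0),
    # lean meat: "None" is minimal, so any intake up to 2 is partial credit
    ("lean_meat", {"lean_meat_per_week": 0}, 0),
    ("lean_meat", {"lean_meat_per_week": 1}, 0.5),
    ("lean_meat", {"lean_meat_per_week": 2}, 0.5),
    ("lean_meat", {"lean_meat_per_week": 3}, 1),
    ("nonmeat_protein", {"nonmeat_protein_per_week": 0.5}, 0),
    ("nonmeat_protein", {"nonmeat_protein_per_week": 2}, 0.5),
    ("nonmeat_protein", {"nonmeat_protein_per_week": 3}, 1),
    ("sugared_bev", {"sugared_bev_per_day": 4}, 0),
    ("sugared_bev", {"sugared_bev_per_day": 3}, 0.5),
    ("sugared_bev", {"sugared_bev_per_day": 0}, 1),
    ("high_fat_meat", {"high_fat_meat_per_week": 3}, 0),
    ("high_fat_meat", {"high_fat_meat_per_week": 2}, 0.5),
    ("high_fat_meat", {"high_fat_meat_per_week": 0.5}, 1),  # "<1" after flooring
    ("fast_food", {"fast_food_per_week": 1}, 0),
    ("fast_food", {"fast_food_per_week": 0.5}, 0.5),
    ("fast_food", {"fast_food_per_week": 0}, 1),
    # fermented dairy is non-linear: both extremes score 0
    ("fermented_dairy", {"fermented_dairy_per_day": 5}, 0),
    ("fermented_dairy", {"fermented_dairy_per_day": 0.5}, 0),
    ("fermented_dairy", {"fermented_dairy_per_day": 1.5}, 0.5),
    ("fermented_dairy", {"fermented_dairy_per_day": 4.5}, 0.5),
    ("fermented_dairy", {"fermented_dairy_per_day": 3}, 1),
    # alcohol: nondrinkers and over-limit drinkers both score 0
    ("alcohol", {"alcohol_days_per_week": 0, "alcohol_drinks_per_day": 0}, 0),
    ("alcohol", {"alcohol_days_per_week": 3, "alcohol_drinks_per_day": 1, "sex": "female"}, 1),
    ("alcohol", {"alcohol_days_per_week": 3, "alcohol_drinks_per_day": 2, "sex": "female"}, 0),
    ("alcohol", {"alcohol_days_per_week": 3, "alcohol_drinks_per_day": 2, "sex": "male"}, 1),
    ("alcohol", {"alcohol_days_per_week": 3, "alcohol_drinks_per_day": 3, "sex": "male"}, 0),
    ("alcohol", {"alcohol_days_per_week": 2, "alcohol_drinks_per_day": 1, "sex": "female"}, 0.5),
])
def test_component_bands(component, fields, expected):
    assert score_component(component, resp(**fields)) == expected


def test_extreme_profiles():
    assert score_hei(DietResponse(**MAXIMAL)).total == 11.0
    assert score_hei(DietResponse(**MINIMAL)).total == 0.0


def test_intermediate_profile_hand_sum():
    """Every component in its partial band except fruit/veg at 3-4/day:
    nine halves plus one point."""
    r = DietResponse(veg_fruit_per_day=3, whole_grains_per_day=1, oily_fish_per_week=0.5,
                     lean_meat_per_week=2, nonmeat_protein_per_week=2, sugared_bev_per_day=2,
                     high_fat_meat_per_week=1, fast_food_per_week=0.5,
                     fermented_dairy_per_day=1.5, alcohol_days_per_week=2,
                     alcohol_drinks_per_day=1, sex="male")
    hs = score_hei(r)
    assert all(v == 0.5 for c, v in hs.component_scores.items() if c != "veg_fruit")
    assert hs.component_scores["veg_fruit"] == 1.0
    assert hs.total == 9 * 0.5 + 1.0


BOUNDARY_VALUES = {
    "veg_fruit_per_day": [0, 0.5, 1, 2, 2.9, 3, 4, 4.9, 5, 8],
    "whole_grains_per_day": [0, 0.5, 1, 2, 2.9, 3, 6],
    "oily_fish_per_week": [0, 0.01, 0.99, 1, 4],
    "lean_meat_per_week": [0, 0.01, 1, 2, 2.5, 3, 6],
    "nonmeat_protein_per_week": [0, 0.99, 1, 2, 2.9, 3, 7],
    "sugared_bev_per_day": [0, 0.5, 1, 3, 3.9, 4, 8],
    "high_fat_meat_per_week": [0, 0.99, 1, 2, 2.9, 3, 7],
    "fast_food_per_week": [0, 0.01, 0.99, 1, 4],
    "fermented_dairy_per_day": [0, 0.99, 1, 1.99, 2, 3.99, 4, 4.99, 5, 7],
    "alcohol_days_per_week": [0, 1, 2, 2.9, 3, 7],
    "alcohol_drinks_per_day": [0, 0.5, 1, 1.5, 2, 2.5, 3],
}


def test_boundary_grid_partitions_cleanly():
    """Every boundary value maps to exactly one band; all scores are valid
    half-point ladder values and totals stay in [0, 11]."""
    ladders = {c: {0, 0.5, 1} for c in COMPONENTS}
    ladders["veg_fruit"] = {0, 0.5, 1, 2}
    field_of = {
        "veg_fruit": "veg_fruit_per_day", "whole_grains": "whole_grains_per_day",
        "oily_fish": "oily_fish_per_week", "lean_meat": "lean_meat_per_week",
        "nonmeat_protein": "nonmeat_protein_per_week", "sugared_bev": "sugared_bev_per_day",
        "high_fat_meat": "high_fat_meat_per_week", "fast_food": "fast_food_per_week",
        "fermented_dairy": "fermented_dairy_per_day",
    }
    for comp, fld in field_of.items():
        for v in BOUNDARY_VALUES[fld]:
            s = score_component(comp, resp(**{fld: v}))
            assert s in ladders[comp], (comp, v, s)
    for sex in ("male", "female"):
        for d in BOUNDARY_VALUES["alcohol_days_per_week"]:
            for q in BOUNDARY_VALUES["alcohol_drinks_per_day"]:
                s = score_component("alcohol", resp(
                    alcohol_days_per_week=d, alcohol_drinks_per_day=q, sex=sex))
                assert s in {0, 0.5, 1}
    # totals over random boundary combinations are multiples of 0.5 in [0, 11]
    rng = np.random.default_rng(0)
    for _ in range(200):
        kw = {f: float(rng.choice(vals)) for f, vals in BOUNDARY_VALUES.items()}
        kw["sex"] = str(rng.choice(["male", "female"]))
        total = score_hei(DietResponse(**kw)).total
        assert 0.0 <= total <= 11.0 and (total * 2) == int(total * 2)


@settings(max_examples=100, deadline=None)
@given(lo=st.floats(0, 8), hi=st.floats(0, 8))
def test_monotone_in_each_food(lo, hi):
    """Direct foods never lower the score with more intake; inverse foods
    never raise it."""
    lo, hi = sorted((lo, hi))
    field_of = {
        "veg_fruit": "veg_fruit_per_day", "whole_grains": "whole_grains_per_day",
        "oily_fish": "oily_fish_per_week", "lean_meat": "lean_meat_per_week",
        "nonmeat_protein": "nonmeat_protein_per_week", "sugared_bev": "sugared_bev_per_day",
        "high_fat_meat": "high_fat_meat_per_week", "fast_food": "fast_food_per_week",
    }
    for comp in DIRECT_COMPONENTS:
        f = field_of[comp]
        assert score_component(comp, resp(**{f: lo})) <= score_component(comp, resp(**{f: hi}))
    for comp in INVERSE_COMPONENTS:
        f = field_of[comp]
        assert score_component(comp, resp(**{f: lo})) >= score_component(comp, resp(**{f: hi}))


def test_missing_answers_exclude_subject():
    with pytest.raises(UnscorableComponent):
        score_hei(resp(oily_fish_per_week=None))
    with pytest.raises(UnscorableComponent):
        score_component("alcohol", resp(sex=None))
    diet = pd.DataFrame([dict(MAXIMAL), {**MAXIMAL, "whole_grains_per_day": math.nan}],
                        index=pd.Index(["a", "b"], name="subject_id"))
    scores, excl = score_hei_table(diet)
    assert list(scores.index) == ["a"]
    assert scores.loc["a", "hei_total"] == 11.0
    assert excl["subject_id"].tolist() == ["b"]
    assert "whole_grains" in excl["reason"].iloc[0]


def test_negative_intake_rejected():
    with pytest.raises(ValueError):
        DietResponse(**{**MAXIMAL, "veg_fruit_per_day": -1})
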