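"""Metabolic syndrome classification (updated ATP III definition).

A subject meets the metabolic syndrome (MetS) definition when at least three
of five criteria are abnormal:

1. central adiposity — waist circumference > 102 cm (men) / > 88 cm (women);
2. elevated triglycerides — >= 150 mg/dL, or drug treatment for
   hypertriglyceridemia;
3. reduced HDL cholesterol — < 40 mg/dL (men) / < 50 mg/dL (women), or drug
   treatment for low HDL-c;
4. elevated blood pressure — systolic >= 130 mmHg or diastolic >= 85 mmHg, or
   antihypertensive medication together with a prior hypertension diagnosis;
5. elevated fasting glucose — >= 100 mg/dL, or drug treatment for
   hyperglycemia.

Inequalities are applied exactly as written (waist strictly >, the others as
shown).  Missing medication flags default to False (conservative toward
non-disease) with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = ["ClinicalProfile", "CRITERIA", "evaluate_criteria", "classify_mets", "classify_mets_table"]

CRITERIA = ("central_adiposity", "high_tg", "low_hdl", "high_bp", "high_glucose")


@dataclass
class ClinicalProfile:
    """Anthropometrics, blood pressure, fasting biomarkers and medication flags."""

    sex: str  # "male" | "female"
    waist_cm: Optional[float] = None
    triglycerides_mg_dl: Optional[float] = None
    hdl_mg_dl: Optional[float] = None
    sbp_mmhg: Optional[float] = None
    dbp_mmhg: Optional[float] = None
    glucose_mg_dl: Optional[float] = None
    on_tg_treatment: Optional[bool] = False
    on_hdl_treatment: Optional[bool] = False
    on_htn_treatment: Optional[bool] = False
    htn_diagnosis: Optional[bool] = False
    on_glucose_treatment: Optional[bool] = False


class UnscorableCriterion(ValueError):
    def __init__(self, criterion: str, reason: str):
        self.criterion = criterion
        super().__init__(f"criterion {criterion!r} unscorable: {reason}")


def _missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def _flag(v, name: str) -> bool:
    if _missing(v):
        warnings.warn(f"medication flag {name} missing; defaulting to False", stacklevel=3)
        return False
    return bool(v)


def evaluate_criteria(profile: ClinicalProfile) -> dict:
    """Evaluate the five ATP III criteria; returns a name -> bool mapping."""
    if profile.sex not in ("male", "female"):
        raise UnscorableCriterion("central_adiposity", "sex required for sex-specific cutoffs")
    male = profile.sex == "male"
    out = {}

    if _missing(profile.waist_cm):
        raise UnscorableCriterion("central_adiposity", "waist missing")
    out["central_adiposity"] = profile.waist_cm > (102.0 if male else 88.0)

    tg_rx = _flag(profile.on_tg_treatment, "on_tg_treatment")
    if _missing(profile.triglycerides_mg_dl) and not tg_rx:
        raise UnscorableCriterion("high_tg", "triglycerides missing")
    out["high_tg"] = tg_rx or (not _missing(profile.triglycerides_mg_dl)
                               and profile.triglycerides_mg_dl >= 150.0)

    hdl_rx = _flag(profile.on_hdl_treatment, "on_hdl_treatment")
    if _missing(profile.hdl_mg_dl) and not hdl_rx:
        raise UnscorableCriterion("low_hdl", "HDL-c missing")
    out["low_hdl"] = hdl_rx or (not _missing(profile.hdl_mg_dl)
                                and profile.hdl_mg_dl < (40.0 if male else 50.0))

    # treated hypertension counts only together with a prior diagnosis
    bp_rx = _flag(profile.on_htn_treatment, "on_htn_treatment") and _flag(
        profile.htn_diagnosis, "htn_diagnosis")
    if (_missing(profile.sbp_mmhg) or _missing(profile.dbp_mmhg)) and not bp_rx:
        raise UnscorableCriterion("high_bp", "blood pressure missing")
    out["high_bp"] = bp_rx or (not _missing(profile.sbp_mmhg) and profile.sbp_mmhg >= 130.0) or (
        not _missing(profile.dbp_mmhg) and profile.dbp_mmhg >= 85.0)

    glu_rx = _flag(profile.on_glucose_treatment, "on_glucose_treatment")
    if _missing(profile.glucose_mg_dl) and not glu_rx:
        raise UnscorableCriterion("high_glucose", "fasting glucose missing")
    out["high_glucose"] = glu_rx or (not _missing(profile.glucose_mg_dl)
                                     and profile.glucose_mg_dl >= 100.0)
    return out


def classify_mets(profile: ClinicalProfile) -> dict:
    """MetS status: positive when at least three of the five criteria hold."""
    crit = evaluate_criteria(profile)
    n = int(sum(crit.values()))
    return {"mets": n >= 3, "n_criteria": n, **crit}


_COLMAP = {
    "sex": "sex",
    "waist_cm": "waist_cm",
    "triglycerides_mg_dl": "triglycerides_mg_dl",
    "hdl_mg_dl": "hdl_mg_dl",
    "sbp_mmhg": "sbp_mmhg",
    "dbp_mmhg": "dbp_mmhg",
    "glucose_mg_dl": "glucose_mg_dl",
    "on_tg_treatment": "on_tg_treatment",
    "on_hdl_treatment": "on_hdl_treatment",
    "on_htn_treatment": "on_htn_treatment",
    "htn_diagnosis": "htn_diagnosis",
    "on_glucose_treatment": "on_glucose_treatment",
}


def classify_mets_table(clinical: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify a clinical table; returns ``(results, exclusions)``."""
    rows, excl = {}, []
    for sid, row in clinical.iterrows():
        kwargs = {f: row[c] for f, c in _COLMAP.items() if c in clinical.columns}
        try:
            rows[sid] = classify_mets(ClinicalProfile(**kwargs))
        except UnscorableCriterion as e:
            excl.append({"subject_id": sid, "reason": str(e)})
    results = pd.DataFrame.from_dict(rows, orient="index")
    results.index.name = clinical.index.name or "subject_id"
    return results, pd.DataFrame(excl, columns=["subject_id", "reason"])
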