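"""10-year ASCVD risk via the 2013 ACC/AHA pooled cohort equations.

The pooled cohort equations (PCE) estimate 10-year risk of a first hard
atherosclerotic cardiovascular event from age, sex, race, total and HDL
cholesterol, systolic blood pressure (treated/untreated), smoking, and
diabetes.  For each race-sex group the published model gives coefficients for
log-transformed covariates (with interaction terms), the group mean of the
linear predictor, and the baseline 10-year survival S0:

    risk = 1 - S0 ** exp(sum_k beta_k * x_k  -  mean_term) .

The calculator is defined for ages 40-79 with total cholesterol 130-320
mg/dL, HDL-c 20-100 mg/dL and systolic blood pressure 90-200 mmHg;
``eligibility_filter`` applies those windows (inclusive at both ends).
Estimated risks can be normalized to a z-scale either by rank-based
inverse-normal (Blom) scoring of the risk distribution, or by applying the
standard-normal inverse CDF to each risk value directly.

Coefficient values below are the published pooled-cohort-equation constants
(Goff et al. 2013, Circulation 129:S49-S73, Appendix 7 Table A).  Subjects of
races other than the two published groups are mapped to the "white or other"
set, as the equations themselves recommend.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lipid_qc import blom_transform

__all__ = [
    "RiskInput",
    "PCE_COEFFICIENTS",
    "ELIGIBILITY_WINDOWS",
    "eligibility_filter",
    "pce_risk",
    "normalize_risk",
]

#: inclusive eligibility windows of the 2013 calculator
ELIGIBILITY_WINDOWS = {
    "age_years": (40.0, 79.0),
    "total_chol_mg_dl": (130.0, 320.0),
    "hdl_mg_dl": (20.0, 100.0),
    "sbp_mmhg": (90.0, 200.0),
}

# term keys: ln_age, ln_age_sq, ln_tc, ln_age_ln_tc, ln_hdl, ln_age_ln_hdl,
# ln_sbp_treated, ln_age_ln_sbp_treated, ln_sbp_untreated,
# ln_age_ln_sbp_untreated, smoker, ln_age_smoker, diabetes
PCE_COEFFICIENTS = {
    ("white_other", "female"): {
        "ln_age": -29.799, "ln_age_sq": 4.884, "ln_tc": 13.540, "ln_age_ln_tc": -3.114,
        "ln_hdl": -13.578, "ln_age_ln_hdl": 3.149, "ln_sbp_treated": 2.019,
        "ln_sbp_untreated": 1.957, "smoker": 7.574, "ln_age_smoker": -1.665,
        "diabetes": 0.661, "mean_term": -29.18, "s0": 0.9665,
    },
    ("white_other", "male"): {
        "ln_age": 12.344, "ln_tc": 11.853, "ln_age_ln_tc": -2.664, "ln_hdl": -7.990,
        "ln_age_ln_hdl": 1.769, "ln_sbp_treated": 1.797, "ln_sbp_untreated": 1.764,
        "smoker": 7.837, "ln_age_smoker": -1.795, "diabetes": 0.658,
        "mean_term": 61.18, "s0": 0.9144,
    },
    ("african_american", "female"): {
        "ln_age": 17.114, "ln_tc": 0.940, "ln_hdl": -18.920, "ln_age_ln_hdl": 4.475,
        "ln_sbp_treated": 29.291, "ln_age_ln_sbp_treated": -6.432,
        "ln_sbp_untreated": 27.820, "ln_age_ln_sbp_untreated": -6.087,
        "smoker": 0.691, "diabetes": 0.874, "mean_term": 86.61, "s0": 0.9533,
    },
    ("african_american", "male"): {
        "ln_age": 2.469, "ln_tc": 0.302, "ln_hdl": -0.307, "ln_sbp_treated": 1.916,
        "ln_sbp_untreated": 1.809, "smoker": 0.549, "diabetes": 0.645,
        "mean_term": 19.54, "s0": 0.8954,
    },
}


@dataclass
class RiskInput:
    """Covariates of the pooled cohort equations for one subject."""

    age_years: float
    sex: str  # "male" | "female"
    race_group: str  # "white_other" | "african_american" (others map to white_other)
    total_chol_mg_dl: float
    hdl_mg_dl: float
    sbp_mmhg: float
    treated_htn: bool
    smoker: bool
    diabetes: bool


def eligibility_filter(subjects: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the calculator's eligibility windows (inclusive endpoints).

    Returns ``(included, exclusions)``; the exclusion log names each violated
    window so boundary handling stays auditable.
    """
    missing = [c for c in ELIGIBILITY_WINDOWS if c not in subjects.columns]
    if missing:
        raise KeyError(f"subjects table missing columns: {missing}")
    ok = pd.Series(True, index=subjects.index)
    reasons = pd.Series("", index=subjects.index)
    for col, (lo, hi) in ELIGIBILITY_WINDOWS.items():
        v = subjects[col]
        bad = ~(v.ge(lo) & v.le(hi))  # NaN counts as ineligible
        ok &= ~bad
        reasons[bad] += f"{col} outside [{lo:g}, {hi:g}]; "
    included = subjects.loc[ok]
    exclusions = pd.DataFrame({"reason": reasons[~ok].str.rstrip("; ")})
    exclusions.index.name = subjects.index.name or "subject_id"
    if included.empty:
        warnings.warn("eligibility filter removed every subject", stacklevel=2)
    return included, exclusions


def _terms(inp: RiskInput) -> dict:
    la, ltc, lhdl, lsbp = (math.log(inp.age_years), math.log(inp.total_chol_mg_dl),
                           math.log(inp.hdl_mg_dl), math.log(inp.sbp_mmhg))
    treated = bool(inp.treated_htn)
    smoker = float(bool(inp.smoker))
    return {
        "ln_age": la, "ln_age_sq": la * la, "ln_tc": ltc, "ln_age_ln_tc": la * ltc,
        "ln_hdl": lhdl, "ln_age_ln_hdl": la * lhdl,
        "ln_sbp_treated": lsbp if treated else 0.0,
        "ln_age_ln_sbp_treated": la * lsbp if treated else 0.0,
        "ln_sbp_untreated": 0.0 if treated else lsbp,
        "ln_age_ln_sbp_untreated": 0.0 if treated else la * lsbp,
        "smoker": smoker, "ln_age_smoker": la * smoker,
        "diabetes": float(bool(inp.diabetes)),
    }


def pce_risk(inp: RiskInput) -> float:
    """Deterministic 10-year ASCVD risk, strictly inside (0, 1)."""
    if inp.sex not in ("male", "female"):
        raise ValueError(f"sex must be male/female, got {inp.sex!r}")
    race = inp.race_group if inp.race_group == "african_american" else "white_other"
    coefs = PCE_COEFFICIENTS[(race, inp.sex)]
    terms = _terms(inp)
    lp = sum(v * terms[k] for k, v in coefs.items() if k not in ("mean_term", "s0"))
    risk = 1.0 - coefs["s0"] ** math.exp(lp - coefs["mean_term"])
    return float(min(max(risk, 1e-15), 1 - 1e-15))


def pce_risk_table(subjects: pd.DataFrame) -> pd.Series:
    """Vector of PCE risks for an eligibility-filtered table."""
    cols = ["age_years", "sex", "race_group", "total_chol_mg_dl", "hdl_mg_dl",
            "sbp_mmhg", "treated_htn", "smoker", "diabetes"]
    missing = [c for c in cols if c not in subjects.columns]
    if missing:
        raise KeyError(f"subjects table missing columns: {missing}")
    risks = subjects.apply(lambda r: pce_risk(RiskInput(**{c: r[c] for c in cols})), axis=1)
    return risks.rename("risk10y")


def normalize_risk(risks, method: str = "rank_inverse_normal") -> np.ndarray:
    """Normalize estimated risks onto a z-scale.

    ``rank_inverse_normal`` (default) applies Blom rank scores to the risk
    distribution; ``direct_quantile`` applies the standard-normal inverse CDF
    to each risk probability elementwise.
    """
    r = np.asarray(risks, dtype=float)
    if r.size == 0:
        raise ValueError("empty risk vector")
    if np.any((r <= 0) | (r >= 1)):
        raise ValueError("risks must lie strictly in (0, 1)")
    if method == "rank_inverse_normal":
        return blom_transform(r)
    if method == "direct_quantile":
        return stats.norm.ppf(r)
    raise ValueError(f"unknown normalization method {method!r}")
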