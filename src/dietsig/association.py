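"""Adjustment-model ladder linking signature, diet index, and health outcomes.

Three nested linear models relate the lipidomic signature to continuous
cardiometabolic outcomes:

* Model I   — sample wave + age + sex + race;
* Model II  — Model I + BMI;
* Model III — Model II + the diet-quality index.

Exposure and continuous outcomes are z-scored on the analysis sample before
fitting, so coefficients are standardized and comparable across biomarkers.
Logistic models relate metabolic syndrome (or its five components) to the
diet index per 1-point change, adjusted for wave, sex, race, age, education,
smoking, and physical activity; effects are reported as odds ratios with Wald
95% confidence intervals.  All fits are complete-case.

Reference categories follow the cohort's descriptive tables: sample wave is
coded core=1 vs refresher, sex men=1 vs women, race white=1 vs non-white,
education as two dummies against a postgraduate reference, and smoking as
never/former dummies against current smokers.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

__all__ = [
    "AssociationResult",
    "TIER_COVARIATES",
    "build_design",
    "fit_tiered_linear",
    "fit_logistic_hei",
    "fit_cvr_association",
    "results_table",
]

MODEL_TIERS = ("I", "II", "III")


@dataclass
class AssociationResult:
    """A single fitted exposure effect with its Wald interval."""

    outcome: str
    tier: str
    coefficient: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    or_scale: bool = False
    covariates: tuple = ()


class CollinearityError(ValueError):
    pass


class SeparationError(ValueError):
    pass


def _dummies(data: pd.DataFrame) -> pd.DataFrame:
    """Encode categorical adjustment variables with the conventional references."""
    out = pd.DataFrame(index=data.index)
    if "wave" in data:
        out["wave_core"] = (data["wave"] == "core").astype(float)
    if "sex" in data:
        out["sex_male"] = (data["sex"] == "male").astype(float)
    if "race" in data:
        out["race_white"] = (data["race"] == "white").astype(float)
    if "age_years" in data:
        out["age_years"] = data["age_years"].astype(float)
    if "education" in data:
        out["edu_hs_or_less"] = (data["education"] == "hs_or_less").astype(float)
        out["edu_college"] = (data["education"] == "college").astype(float)
    if "smoking" in data:
        out["smoke_never"] = (data["smoking"] == "never").astype(float)
        out["smoke_former"] = (data["smoking"] == "former").astype(float)
    if "physical_activity" in data:
        out["physical_activity"] = data["physical_activity"].astype(float)
    if "bmi" in data:
        out["bmi"] = data["bmi"].astype(float)
    return out


#: adjustment sets of the three nested linear models (column names after encoding)
TIER_COVARIATES = {
    "I": ("wave_core", "age_years", "sex_male", "race_white"),
    "II": ("wave_core", "age_years", "sex_male", "race_white", "bmi"),
    "III": ("wave_core", "age_years", "sex_male", "race_white", "bmi", "hei_total"),
}

LOGISTIC_COVARIATES = ("wave_core", "sex_male", "race_white", "age_years",
                       "edu_hs_or_less", "edu_college", "smoke_never", "smoke_former",
                       "physical_activity")


def _check_collinear(X: pd.DataFrame) -> None:
    M = X.to_numpy(dtype=float)
    # scale columns so rank detection is unit-free; constant column handled upstream
    sd = M.std(axis=0)
    sd[sd == 0] = 1.0
    Ms = (M - M.mean(axis=0)) / sd
    rank = np.linalg.matrix_rank(Ms)
    if rank < Ms.shape[1]:
        _, R, piv = scipy.linalg.qr(Ms, pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] < 1e-8 * diag[0]]
        bad += [X.columns[p] for p in piv[len(diag):]]
        raise CollinearityError(f"collinear covariates: {sorted(set(map(str, bad)))}")


def _zscore(v: pd.Series) -> pd.Series:
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError(f"zero variance in {v.name!r}")
    return (v - v.mean()) / sd


def build_design(data: pd.DataFrame, covariates: tuple) -> pd.DataFrame:
    """Encoded covariate block for a model tier (no intercept column)."""
    enc = _dummies(data)
    if "hei_total" in covariates:
        enc["hei_total"] = data["hei_total"].astype(float)
    missing = [c for c in covariates if c not in enc.columns]
    if missing:
        raise KeyError(f"cannot build covariates {missing}; check input columns")
    return enc[list(covariates)]


def _fit_linear(data, outcome, exposure, covariates, tier, standardize=True):
    frame = pd.concat(
        [data[[outcome, exposure]].astype(float), build_design(data, covariates)], axis=1)
    frame = frame.dropna()
    n = len(frame)
    if n < 10 * (len(covariates) + 1):
        raise ValueError(
            f"only {n} complete cases for {len(covariates) + 1} coefficients; need >= 10x")
    y = _zscore(frame[outcome]) if standardize else frame[outcome]
    x = _zscore(frame[exposure]) if standardize else frame[exposure]
    X = pd.concat([x.rename(exposure), frame[list(covariates)]], axis=1)
    _check_collinear(X)
    fit = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy())).fit()
    lo, hi = fit.conf_int()[1]
    return AssociationResult(
        outcome=outcome, tier=tier, coefficient=float(fit.params[1]),
        ci_low=float(lo), ci_high=float(hi), p_value=float(fit.pvalues[1]),
        n=n, or_scale=False, covariates=tuple(covariates))


def fit_tiered_linear(data: pd.DataFrame, outcome: str, exposure: str = "signature",
                      tiers=MODEL_TIERS, standardize: bool = True) -> list[AssociationResult]:
    """Standardized linear effect of the exposure on a continuous outcome per tier."""
    results = []
    for tier in tiers:
        cov = TIER_COVARIATES[tier]
        if outcome == "bmi" and "bmi" in cov:
            continue  # BMI cannot adjust for itself (tier I only, as reported)
        results.append(_fit_linear(data, outcome, exposure, cov, tier, standardize))
    return results


def fit_logistic_hei(data: pd.DataFrame, outcome: str,
                     exposure: str = "hei_total") -> AssociationResult:
    """Odds ratio per 1-point diet index for a binary outcome (MetS or component)."""
    frame = pd.concat(
        [data[[outcome]], data[[exposure]].astype(float),
         build_design(data, LOGISTIC_COVARIATES)], axis=1).dropna()
    y = frame[outcome].astype(float)
    if set(y.unique()) - {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} is not binary")
    if y.nunique() < 2:
        raise ValueError(f"outcome {outcome!r} has a single class")
    X = pd.concat([frame[[exposure]], frame[list(LOGISTIC_COVARIATES)]], axis=1)
    _check_collinear(X)
    try:
        fit = sm.Logit(y.to_numpy(), sm.add_constant(X.to_numpy())).fit(disp=0, maxiter=200)
    except Exception as e:  # statsmodels raises PerfectSeparationError subclasses
        raise SeparationError(
            f"logistic fit failed for {outcome!r} (possible separation); "
            f"consider a penalized fit: {e}") from e
    if not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3:
        raise SeparationError(f"separation suspected for {outcome!r}: unstable Wald SE")
    beta, se = float(fit.params[1]), float(fit.bse[1])
    return AssociationResult(
        outcome=outcome, tier="logistic", coefficient=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p_value=float(fit.pvalues[1]), n=len(frame), or_scale=True,
        covariates=LOGISTIC_COVARIATES)


def fit_cvr_association(data: pd.DataFrame, outcome: str = "cvr_normalized",
                        exposure: str = "signature",
                        or_view: bool = True) -> list[AssociationResult]:
    """Tiered linear models of normalized cardiovascular risk on the signature.

    Restricted upstream to calculator-eligible subjects.  When ``or_view`` is
    set, each tier also yields a derived odds-ratio-scale representation
    (exp of the standardized coefficient), clearly flagged ``or_scale``.
    """
    results = fit_tiered_linear(data, outcome, exposure)
    if or_view:
        for res in list(results):
            results.append(AssociationResult(
                outcome=res.outcome, tier=res.tier, coefficient=float(np.exp(res.coefficient)),
                ci_low=float(np.exp(res.ci_low)), ci_high=float(np.exp(res.ci_high)),
                p_value=res.p_value, n=res.n, or_scale=True, covariates=res.covariates))
    return results


def results_table(results) -> pd.DataFrame:
    """Tidy one-row-per-fit results table."""
    rows = []
    for r in results:
        d = asdict(r)
        d["covariates"] = ";".join(d["covariates"])
        rows.append(d)
    return pd.DataFrame(rows)
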