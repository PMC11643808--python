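"""End-to-end orchestration: simulate/load -> score -> QC -> signature ->
MetS -> CVD risk -> association models, with a reproducibility manifest.

The pipeline consumes delimited text tables only.  Every subject exclusion
(missing questionnaire answers, unscorable clinical criteria, calculator
eligibility) is logged with a reason, and the manifest records seeds, stage
subject counts and the fitted penalty so a run is reproducible from its
configuration alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (fit_cvr_association, fit_logistic_hei, fit_tiered_linear,
                          results_table)
from .cvd_risk import eligibility_filter, normalize_risk, pce_risk_table
from .hei import score_hei_table
from .lipid_qc import (LOD_THRESHOLD_DEFAULT, filter_by_lod, handle_below_lod_values,
                       standardize)
from .mets import classify_mets_table
from .signature import (apply_signature, evaluate_signature, fit_lasso,
                        loocv_training_scores, summarize_classes)
from .synthetic import GeneratorConfig, generate, read_bundle, write_bundle

__all__ = ["PipelineConfig", "run_all", "validate_tables"]

_KNOWN_KEYS = {
    "cohort_dir", "out_dir", "seed", "simulate", "lod_threshold", "below_lod_policy",
    "lambda_rule", "normalize_method", "biomarker_outcomes", "n_train", "n_test",
    "n_lipids", "n_signal_lipids", "diet_lipid_coupling", "mets_target_prevalence",
    "loocv",
}

#: continuous outcomes of the tiered ladder (clinical column names)
DEFAULT_BIOMARKER_OUTCOMES = ("bmi", "ldl_mg_dl", "hdl_mg_dl", "homa_ir",
                              "insulin_uiu_ml", "glucose_mg_dl", "hba1c_pct",
                              "il6_pg_ml", "crp_mg_l")


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    seed: int
    out_dir: str
    cohort_dir: str | None = None  # read an existing bundle instead of simulating
    simulate: dict = field(default_factory=dict)  # GeneratorConfig overrides
    lod_threshold: float = LOD_THRESHOLD_DEFAULT
    below_lod_policy: str = "rank_low"
    lambda_rule: str = "cv_min"
    normalize_method: str = "rank_inverse_normal"
    biomarker_outcomes: tuple = DEFAULT_BIOMARKER_OUTCOMES
    loocv: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_keys = {"n_train", "n_test", "n_lipids", "n_signal_lipids",
                    "diet_lipid_coupling", "mets_target_prevalence"}
        sim = {k: raw.pop(k) for k in list(raw) if k in sim_keys}
        sim.update(raw.pop("simulate", {}) or {})
        raw["simulate"] = sim
        if "biomarker_outcomes" in raw:
            raw["biomarker_outcomes"] = tuple(raw["biomarker_outcomes"])
        return cls(**raw)


def validate_tables(bundle) -> pd.DataFrame:
    """Schema/range checks across a bundle; returns a table of failures."""
    problems = []

    def flag(table, subject, check):
        problems.append({"table": table, "subject_id": subject, "check": check})

    for name, df in (("demographics", bundle.demographics), ("diet", bundle.diet),
                     ("clinical", bundle.clinical), ("lipids", bundle.lipids.values)):
        if df.index.has_duplicates:
            for sid in df.index[df.index.duplicated()].unique():
                flag(name, sid, "duplicated subject ID")
    base = bundle.demographics.index
    for name, df in (("diet", bundle.diet), ("clinical", bundle.clinical),
                     ("lipids", bundle.lipids.values)):
        if not df.index.equals(base):
            flag(name, "", "subject IDs do not align with demographics")
    if "waist_cm" in bundle.clinical:
        for sid in bundle.clinical.index[bundle.clinical["waist_cm"] <= 0]:
            flag("clinical", sid, "non-positive waist circumference")
    for col in ("hdl_mg_dl", "triglycerides_mg_dl", "glucose_mg_dl", "sbp_mmhg"):
        if col in bundle.clinical:
            for sid in bundle.clinical.index[bundle.clinical[col] <= 0]:
                flag("clinical", sid, f"non-positive {col}")
    neg = bundle.lipids.values.lt(0).any(axis=1)
    for sid in bundle.lipids.values.index[neg]:
        flag("lipids", sid, "negative concentration")
    return pd.DataFrame(problems, columns=["table", "subject_id", "check"])


def run_all(config: PipelineConfig) -> Path:
    """Execute every stage and write result tables plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed, "stages": {}}

    # --- cohort ------------------------------------------------------------
    if config.cohort_dir:
        bundle = read_bundle(config.cohort_dir)
        manifest["cohort"] = str(config.cohort_dir)
    else:
        gcfg = GeneratorConfig(seed=config.seed, **config.simulate)
        bundle = generate(gcfg)
        write_bundle(bundle, out / "cohort")
        manifest["cohort"] = "simulated"
    report = validate_tables(bundle)
    if not report.empty:
        report.to_csv(out / "validation_failures.csv", index=False)
        raise ValueError(f"input validation failed with {len(report)} problems "
                         f"(see validation_failures.csv)")
    n0 = len(bundle.demographics)
    manifest["stages"]["input"] = n0

    # --- diet index --------------------------------------------------------
    hei, hei_excl = score_hei_table(bundle.diet)
    hei.to_csv(out / "hei.csv")
    hei_excl.to_csv(out / "exclusions_hei.csv", index=False)
    manifest["stages"]["hei_scored"] = len(hei)

    # --- lipid QC ----------------------------------------------------------
    lip = filter_by_lod(bundle.lipids, config.lod_threshold)
    lip = handle_below_lod_values(lip, config.below_lod_policy)
    std = standardize(lip)
    std.values.to_csv(out / "lipids_std.csv")
    manifest["stages"]["species_retained"] = len(std.retained_species)

    # --- signature ---------------------------------------------------------
    wave = bundle.demographics["wave"]
    train_ids = hei.index.intersection(wave.index[wave == "core"])
    test_ids = hei.index.intersection(wave.index[wave == "refresher"])
    Xtr, ytr = std.values.loc[train_ids], hei.loc[train_ids, "hei_total"]
    model = fit_lasso(Xtr, ytr, config.lambda_rule, seed=config.seed)
    model.save(out / "model")
    manifest["lambda"] = model.lambda_
    manifest["n_selected"] = int(model.weights.size)
    if not bundle.lipids.species_meta.empty and model.weights.size:
        summarize_classes(model, bundle.lipids.species_meta).to_csv(out / "signature_classes.csv")

    if config.loocv:
        train_scores = loocv_training_scores(Xtr, ytr, model.lambda_)
    else:
        train_scores = apply_signature(model, Xtr)
    parts = [pd.DataFrame({"score": train_scores.scores,
                           "provenance": train_scores.provenance})]
    eval_out = {"train": (evaluate_signature(train_scores, ytr)
                          if train_scores.scores.std() > 0 else None)}
    if len(test_ids):
        test_scores = apply_signature(model, std.values.loc[test_ids])
        parts.append(pd.DataFrame({"score": test_scores.scores,
                                   "provenance": test_scores.provenance}))
        eval_out["test"] = (evaluate_signature(test_scores, hei.loc[test_ids, "hei_total"])
                            if test_scores.scores.std() > 0 else None)
    scores = pd.concat(parts)
    scores.index.name = "subject_id"
    scores.to_csv(out / "signature_scores.csv")
    combined = scores["score"].reindex(hei.index).dropna()
    if combined.std() > 0:
        eval_out["combined"] = evaluate_signature(
            combined.to_numpy(), hei.loc[combined.index, "hei_total"].to_numpy())
    manifest["signature_eval"] = eval_out
    manifest["stages"]["signature_scored"] = int(len(scores))

    # --- metabolic syndrome ------------------------------------------------
    mets, mets_excl = classify_mets_table(bundle.clinical)
    mets.to_csv(out / "mets.csv")
    mets_excl.to_csv(out / "exclusions_mets.csv", index=False)
    manifest["stages"]["mets_classified"] = len(mets)

    # --- cardiovascular risk -----------------------------------------------
    risk_in = bundle.clinical.join(bundle.demographics[["age_years", "race", "smoking"]])
    risk_in["race_group"] = np.where(risk_in["race"] == "african_american",
                                     "african_american", "white_other")
    risk_in["smoker"] = risk_in["smoking"] == "current"
    risk_in["treated_htn"] = risk_in.get("on_htn_treatment", False)
    # diabetes: explicit treatment, or HbA1c at/above the diagnostic 6.5%
    risk_in["diabetes"] = (risk_in.get("on_glucose_treatment", False)
                           | (risk_in.get("hba1c_pct", pd.Series(0.0, index=risk_in.index))
                              >= 6.5))
    eligible, risk_excl = eligibility_filter(risk_in)
    risk_excl.to_csv(out / "exclusions_risk.csv")
    risks = pce_risk_table(eligible)
    risk_df = pd.DataFrame({"risk10y": risks})
    risk_df["normalized"] = normalize_risk(risks.to_numpy(), config.normalize_method)
    risk_df["method"] = config.normalize_method
    risk_df.to_csv(out / "risk.csv")
    manifest["stages"]["risk_eligible"] = len(eligible)

    # --- association models ------------------------------------------------
    merged = bundle.demographics.join(bundle.clinical.drop(columns=["sex"]))
    merged = merged.join(hei[["hei_total"]]).join(scores[["score"]].rename(
        columns={"score": "signature"}))
    crit_cols = ["mets", "central_adiposity", "high_tg", "low_hdl", "high_bp", "high_glucose"]
    merged = merged.join(mets[crit_cols].astype(float))
    results = []
    for outcome in config.biomarker_outcomes:
        if outcome in merged:
            results.extend(fit_tiered_linear(merged, outcome))
    for outcome in ("mets", "central_adiposity", "high_tg", "low_hdl", "high_bp",
                    "high_glucose"):
        if outcome in merged and merged[outcome].nunique() == 2:
            results.append(fit_logistic_hei(merged, outcome))
    cvr = merged.join(risk_df[["normalized"]].rename(columns={"normalized": "cvr_normalized"}),
                      how="inner")
    results.extend(fit_cvr_association(cvr))
    results_table(results).to_csv(out / "associations.csv", index=False)
    manifest["stages"]["association_fits"] = len(results)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return out
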