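"""Two-wave synthetic cohort generator with planted, recoverable effects.

The generator emulates the statistical structure the analysis pipeline
assumes, so every downstream stage is testable without access to restricted
cohort data:

* a latent diet-quality factor ``D ~ N(0, 1)`` per subject;
* questionnaire responses built by thresholding per-component noisy copies of
  ``D`` into the index's scoring bands and sampling a serving count inside the
  chosen band, calibrated so the scored index has mean ~5.8, SD ~1.5 and
  correlates with ``D`` above 0.9;
* a lipid panel in which a planted subset of species loads on ``D`` with
  geometrically decaying loadings, scaled so the *population* correlation
  between the best linear lipid combination and the scored diet index equals
  a requested coupling ``rho``; remaining species are independent noise, and
  the lowest-concentration cells per species are flagged below-LOD;
* cardiometabolic biomarkers driven by ``D`` with the published sign
  structure (HDL-c positive; insulin, HOMA-IR, IL-6, CRP, BMI negative) plus
  age/sex/adiposity confounding;
* metabolic-syndrome component fields shifted by a common offset, solved
  numerically so the classified prevalence matches a target;
* demographics roughly matching the cohort's margins (sex ~45/55, ~75%
  white, three education bands, ages 35-90, two sampling waves).

Ground truth (the latent factor, planted loadings, planted biomarker
effects) is carried in a sidecar that the analysis pipeline never reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .hei import COMPONENTS, score_hei_table
from .lipid_qc import LipidMatrix

__all__ = ["GeneratorConfig", "CohortBundle", "generate", "write_bundle", "read_bundle"]

#: Table-4-style standardized effects of latent diet quality on biomarkers.
DEFAULT_BIOMARKER_EFFECTS = {
    "hdl": 0.25, "insulin": -0.25, "il6": -0.26, "crp": -0.24,
    "bmi": -0.21, "glucose": -0.10, "hba1c": -0.08, "ldl": -0.03,
}

#: share of a component's latent variance carried by D (rest is component noise)
COMPONENT_SIGNAL_SHARE = 0.80

# Per-component band probabilities (minimal, intermediate, maximal[, double]).
# Calibrated once (Monte-Carlo) so the scored index lands near mean 5.8 /
# SD 1.55 while keeping its correlation with D above 0.9; margins are
# compressed toward the intermediate band relative to survey data to keep the
# 23-level discrete total tightly coupled to the latent factor.  Healthiest
# margins sit on lean meat, non-meat protein and sugared beverages, lowest on
# oily fish, fast food and alcohol.
BAND_PROBS = {
    "veg_fruit": (0.018, 0.282, 0.675, 0.025),
    "whole_grains": (0.021, 0.859, 0.12),
    "oily_fish": (0.06, 0.885, 0.055),
    "lean_meat": (0.018, 0.792, 0.19),
    "nonmeat_protein": (0.018, 0.762, 0.22),
    "sugared_bev": (0.018, 0.692, 0.29),
    "high_fat_meat": (0.021, 0.809, 0.17),
    "fast_food": (0.052, 0.873, 0.075),
    "fermented_dairy": (0.06, 0.865, 0.075),
    "alcohol": (0.155, 0.77, 0.075),
}

#: default geometric decay of planted lipid loadings (a handful of species
#: dominate, as in observed diet signatures)
LOADING_DECAY = 0.65

LIPID_CLASSES = ("TG", "PC", "PE", "PE-O", "SM", "CE", "LPC", "DG", "PI", "FA")
LIPID_CLASS_PROBS = (0.25, 0.20, 0.08, 0.08, 0.09, 0.08, 0.06, 0.06, 0.04, 0.06)


@dataclass
class GeneratorConfig:
    """Study-condition knobs of the synthetic cohort."""

    seed: int
    n_train: int = 1200
    n_test: int = 850
    n_lipids: int = 400
    n_signal_lipids: int = 57
    diet_lipid_coupling: float = 0.4  # population signature-index correlation rho
    biomarker_effects: dict = field(default_factory=lambda: dict(DEFAULT_BIOMARKER_EFFECTS))
    mets_target_prevalence: float = 0.37
    hei_mean: float = 5.8
    hei_sd: float = 1.5
    below_lod_fraction: float = 0.02  # censored share of cells per retained-quality species
    n_lod_heavy: int = 20  # noise species censored heavily (removed by the QC filter)
    diet_missing_rate: float = 0.0
    loading_decay: float = LOADING_DECAY  # 1.0 = equal loadings across signal species

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_train <= 0 or self.n_test < 0 or self.n_lipids <= 0:
            raise ValueError("cohort sizes must be positive (n_test may be 0)")
        if not (0 <= self.diet_lipid_coupling < 1):
            raise ValueError("diet_lipid_coupling must lie in [0, 1)")
        if self.n_signal_lipids > self.n_lipids:
            raise ValueError("n_signal_lipids cannot exceed n_lipids")


@dataclass
class CohortBundle:
    """Aligned demographics, diet, lipid and clinical tables plus ground truth."""

    demographics: pd.DataFrame
    diet: pd.DataFrame
    lipids: LipidMatrix
    clinical: pd.DataFrame
    ground_truth: dict


# ---------------------------------------------------------------------------
# diet questionnaire
# ---------------------------------------------------------------------------

def _band_indices(u: np.ndarray, probs) -> np.ndarray:
    """Assign latent values to bands at the standard-normal quantile cuts."""
    cuts = np.array([np.sum(probs[: i + 1]) for i in range(len(probs) - 1)])
    from scipy.stats import norm
    return np.searchsorted(norm.ppf(cuts), u, side="left")


def _sample_diet(rng, band, component, sex_male):
    """Serving values consistent with each subject's assigned scoring band."""
    n = band.size
    v = np.zeros(n)
    if component == "veg_fruit":
        v[band == 1] = rng.integers(1, 3, (band == 1).sum())
        v[band == 2] = rng.integers(3, 5, (band == 2).sum())
        v[band == 3] = rng.integers(5, 9, (band == 3).sum())
    elif component == "whole_grains":
        v[band == 1] = rng.integers(1, 3, (band == 1).sum())
        v[band == 2] = rng.integers(3, 6, (band == 2).sum())
    elif component == "oily_fish":
        v[band == 1] = np.round(rng.uniform(0.25, 0.9, (band == 1).sum()), 2)
        v[band == 2] = rng.integers(1, 4, (band == 2).sum())
    elif component == "lean_meat":
        v[band == 1] = rng.integers(1, 3, (band == 1).sum())
        v[band == 2] = rng.integers(3, 7, (band == 2).sum())
    elif component == "nonmeat_protein":
        v[band == 1] = rng.integers(1, 3, (band == 1).sum())
        v[band == 2] = rng.integers(3, 8, (band == 2).sum())
    elif component == "sugared_bev":
        v[band == 0] = rng.integers(4, 9, (band == 0).sum())
        v[band == 1] = rng.integers(1, 4, (band == 1).sum())
    elif component == "high_fat_meat":
        v[band == 0] = rng.integers(3, 8, (band == 0).sum())
        v[band == 1] = rng.integers(1, 3, (band == 1).sum())
    elif component == "fast_food":
        v[band == 0] = rng.integers(1, 5, (band == 0).sum())
        v[band == 1] = np.round(rng.uniform(0.2, 0.8, (band == 1).sum()), 2)
    elif component == "fermented_dairy":
        m0 = band == 0
        v[m0] = rng.choice([0.0, 0.5, 5.0, 6.0], m0.sum(), p=[0.5, 0.25, 0.15, 0.1])
        v[band == 1] = rng.choice([1.0, 1.5, 4.0, 4.5], (band == 1).sum())
        v[band == 2] = rng.choice([2.0, 2.5, 3.0, 3.5], (band == 2).sum())
    else:
        raise KeyError(component)
    return v


def _sample_alcohol(rng, band, sex_male):
    """(days/week, drinks/day) pairs per band; limits are sex-specific."""
    n = band.size
    days = np.zeros(n)
    drinks = np.zeros(n)
    limit = np.where(sex_male, 2, 1)
    m0, m1, m2 = band == 0, band == 1, band == 2
    # minimal band: mostly nondrinkers, some over-limit drinkers
    over = m0 & (rng.random(n) < 0.25)
    days[over] = rng.integers(1, 8, over.sum())
    drinks[over] = limit[over] + rng.integers(1, 4, over.sum())
    days[m1] = rng.integers(1, 3, m1.sum())
    drinks[m1] = np.where(sex_male[m1] & (rng.random(m1.sum()) < 0.5), 2, 1)
    days[m2] = rng.integers(3, 8, m2.sum())
    drinks[m2] = np.where(sex_male[m2] & (rng.random(m2.sum()) < 0.5), 2, 1)
    return days, drinks


def _generate_diet(rng, D, sex_male, missing_rate):
    n = D.size
    w = COMPONENT_SIGNAL_SHARE
    diet = pd.DataFrame(index=pd.RangeIndex(n))
    planted = {}
    for comp in COMPONENTS:
        u = np.sqrt(w) * D + np.sqrt(1 - w) * rng.standard_normal(n)
        band = _band_indices(u, BAND_PROBS[comp])
        planted[comp] = band
        if comp == "alcohol":
            days, drinks = _sample_alcohol(rng, band, sex_male)
            diet["alcohol_days_per_week"] = days
            diet["alcohol_drinks_per_day"] = drinks
        else:
            colname = {
                "veg_fruit": "veg_fruit_per_day", "whole_grains": "whole_grains_per_day",
                "oily_fish": "oily_fish_per_week", "lean_meat": "lean_meat_per_week",
                "nonmeat_protein": "nonmeat_protein_per_week",
                "sugared_bev": "sugared_bev_per_day", "high_fat_meat": "high_fat_meat_per_week",
                "fast_food": "fast_food_per_week", "fermented_dairy": "fermented_dairy_per_day",
            }[comp]
            diet[colname] = _sample_diet(rng, band, comp, sex_male)
    if missing_rate > 0:
        numeric = [c for c in diet.columns]
        mask = rng.random((n, len(numeric))) < missing_rate
        vals = diet[numeric].to_numpy(dtype=float)
        vals[mask] = np.nan
        diet[numeric] = vals
    diet["sex"] = np.where(sex_male, "male", "female")
    return diet, planted


# ---------------------------------------------------------------------------
# lipid panel
# ---------------------------------------------------------------------------

def _loadings(k: int, coupling: float, r_h: float, decay: float = LOADING_DECAY) -> np.ndarray:
    """Geometric-decay loadings scaled so the optimal-combination correlation
    with the scored index equals ``coupling``."""
    if coupling == 0 or k == 0:
        return np.zeros(k)
    c = coupling / r_h  # required correlation with the latent factor
    if not (0 < c < 1):
        raise ValueError(
            f"infeasible coupling {coupling:.3f}: the scored index correlates with the "
            f"latent factor at {r_h:.3f}, so the coupling must be below {r_h:.3f}")
    g = decay ** np.arange(k)
    target = c * c / (1 - c * c)  # required sum of l^2/(1-l^2)

    def s(t):
        l2 = np.minimum((t * g) ** 2, 1 - 1e-12)
        return np.sum(l2 / (1 - l2))

    lo, hi = 0.0, 1.0 / g[0]
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if s(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi) * g


def _species_names(rng, n_lipids):
    classes = rng.choice(LIPID_CLASSES, n_lipids, p=LIPID_CLASS_PROBS)
    names, meta = [], []
    for i, cls in enumerate(classes):
        carbons = int(rng.integers(30, 60)) if cls in ("TG", "DG") else int(rng.integers(14, 42))
        doubles = int(rng.integers(0, 8))
        names.append(f"{cls}({carbons}:{doubles})#{i:03d}")
        meta.append({"lipid_class": cls, "fa_composition": f"{carbons}:{doubles}"})
    meta = pd.DataFrame(meta, index=pd.Index(names, name="species"))
    return names, meta


def _generate_lipids(rng, D, hei_z, cfg: GeneratorConfig):
    n = D.size
    p, k = cfg.n_lipids, cfg.n_signal_lipids
    ok = ~np.isnan(hei_z)
    r_h = float(np.corrcoef(hei_z[ok], D[ok])[0, 1]) if np.std(hei_z[ok]) > 0 else 0.0
    load = _loadings(k, cfg.diet_lipid_coupling, r_h, cfg.loading_decay)
    signs = rng.choice([-1.0, 1.0], k)
    load = load * signs

    names, meta = _species_names(rng, p)
    signal_idx = rng.choice(p, k, replace=False)
    Z = rng.standard_normal((n, p))
    for j, idx in enumerate(signal_idx):
        l = load[j]
        Z[:, idx] = l * D + np.sqrt(max(1 - l * l, 0.0)) * Z[:, idx]

    # monotone map onto positive concentration units (species-specific lognormal)
    mu = rng.uniform(np.log(0.05), np.log(50.0), p)
    sigma = rng.uniform(0.3, 0.8, p)
    conc = np.exp(mu + sigma * Z)

    # censor the lowest cells per species; a subset of noise species heavily
    frac = np.full(p, cfg.below_lod_fraction)
    noise_idx = np.setdiff1d(np.arange(p), signal_idx)
    heavy = rng.choice(noise_idx, min(cfg.n_lod_heavy, noise_idx.size), replace=False)
    frac[heavy] = rng.uniform(0.25, 0.6, heavy.size)
    below = np.zeros((n, p), dtype=bool)
    for j in range(p):
        m = int(np.floor(frac[j] * n))
        if m > 0:
            below[np.argsort(conc[:, j])[:m], j] = True

    values = pd.DataFrame(conc, columns=names)
    mask = pd.DataFrame(below, columns=names)
    truth_loadings = pd.DataFrame(
        {"species": [names[i] for i in signal_idx], "loading": load}).set_index("species")
    return LipidMatrix(values, mask, meta), truth_loadings, r_h


# ---------------------------------------------------------------------------
# clinical profile and biomarkers
# ---------------------------------------------------------------------------

def _noisy(rng, mean_part, explained_var):
    """mean_part + independent noise bringing the latent to ~unit variance."""
    resid = max(1.0 - explained_var, 0.05)
    return mean_part + np.sqrt(resid) * rng.standard_normal(mean_part.shape)


def _generate_clinical(rng, D, demo, eff, target_prev):
    n = D.size
    male = (demo["sex"] == "male").to_numpy()
    age_z = (demo["age_years"].to_numpy() - 62.5) / 15.9

    g = {k: float(eff.get(k, 0.0)) for k in DEFAULT_BIOMARKER_EFFECTS}
    bmi_z = _noisy(rng, g["bmi"] * D + 0.10 * age_z, g["bmi"] ** 2 + 0.01)
    hdl_z = _noisy(rng, g["hdl"] * D - 0.25 * bmi_z + 0.35 * (~male),
                   g["hdl"] ** 2 + 0.0625 + 0.03)
    ldl_z = _noisy(rng, g["ldl"] * D + 0.15 * age_z, g["ldl"] ** 2 + 0.0225)
    tg_z = _noisy(rng, -0.10 * D + 0.35 * bmi_z, 0.01 + 0.1225)
    glu_z = _noisy(rng, g["glucose"] * D + 0.30 * bmi_z + 0.20 * age_z,
                   g["glucose"] ** 2 + 0.09 + 0.04)
    ins_z = _noisy(rng, g["insulin"] * D + 0.45 * bmi_z, g["insulin"] ** 2 + 0.2025)
    hba_z = _noisy(rng, g["hba1c"] * D + 0.25 * bmi_z + 0.20 * age_z,
                   g["hba1c"] ** 2 + 0.0625 + 0.04)
    il6_z = _noisy(rng, g["il6"] * D + 0.35 * bmi_z + 0.15 * age_z,
                   g["il6"] ** 2 + 0.1225 + 0.0225)
    crp_z = _noisy(rng, g["crp"] * D + 0.45 * bmi_z, g["crp"] ** 2 + 0.2025)
    waist_z = _noisy(rng, 0.85 * bmi_z, 0.7225)
    bp_z = _noisy(rng, -0.05 * D + 0.25 * bmi_z + 0.30 * age_z, 0.0025 + 0.0625 + 0.09)
    dbp_z = _noisy(rng, 0.70 * bp_z, 0.49)

    # medication flags tied to the matching latent
    on_htn = rng.random(n) < expit(-2.2 + 1.3 * bp_z)
    htn_dx = on_htn & (rng.random(n) < 0.85)
    on_tg_rx = rng.random(n) < expit(-3.2 + 1.0 * tg_z)
    on_hdl_rx = rng.random(n) < expit(-4.0 - 0.8 * hdl_z)
    on_glu_rx = rng.random(n) < expit(-3.2 + 1.4 * glu_z)

    def units(delta):
        """Clinical units from latents; delta shifts the five criterion axes."""
        c = {}
        c["bmi"] = np.maximum(29.5 + 6.2 * bmi_z, 16.0)
        c["waist_cm"] = np.where(male, 101.0 + 13.0 * (waist_z + delta),
                                 90.0 + 14.0 * (waist_z + delta))
        c["triglycerides_mg_dl"] = np.exp(4.75 + 0.55 * (tg_z + delta))
        c["hdl_mg_dl"] = np.maximum(55.0 + 16.0 * (hdl_z - delta), 10.0)
        c["sbp_mmhg"] = np.maximum(122.0 + 16.0 * (bp_z + delta), 80.0)
        c["dbp_mmhg"] = np.maximum(74.0 + 10.0 * (dbp_z + delta), 45.0)
        c["glucose_mg_dl"] = np.maximum(97.0 + 13.0 * (glu_z + delta), 55.0)
        return c

    def prevalence(delta):
        c = units(delta)
        crit = (
            (c["waist_cm"] > np.where(male, 102.0, 88.0)).astype(int)
            + ((c["triglycerides_mg_dl"] >= 150.0) | on_tg_rx).astype(int)
            + ((c["hdl_mg_dl"] < np.where(male, 40.0, 50.0)) | on_hdl_rx).astype(int)
            + ((c["sbp_mmhg"] >= 130.0) | (c["dbp_mmhg"] >= 85.0) | (on_htn & htn_dx)).astype(int)
            + ((c["glucose_mg_dl"] >= 100.0) | on_glu_rx).astype(int)
        )
        return float(np.mean(crit >= 3))

    lo, hi = -2.0, 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if prevalence(mid) < target_prev:
            lo = mid
        else:
            hi = mid
    delta = 0.5 * (lo + hi)
    c = units(delta)

    clinical = pd.DataFrame({
        "sex": demo["sex"].to_numpy(),
        "waist_cm": np.round(c["waist_cm"], 1),
        "triglycerides_mg_dl": np.round(c["triglycerides_mg_dl"], 1),
        "hdl_mg_dl": np.round(c["hdl_mg_dl"], 1),
        "ldl_mg_dl": np.round(np.maximum(115.0 + 32.0 * ldl_z, 30.0), 1),
        "sbp_mmhg": np.round(c["sbp_mmhg"], 1),
        "dbp_mmhg": np.round(c["dbp_mmhg"], 1),
        "glucose_mg_dl": np.round(c["glucose_mg_dl"], 1),
        "insulin_uiu_ml": np.round(np.exp(2.3 + 0.55 * ins_z), 2),
        "hba1c_pct": np.round(np.maximum(5.7 + 0.55 * hba_z, 4.0), 2),
        "il6_pg_ml": np.round(np.exp(0.8 + 0.7 * il6_z), 2),
        "crp_mg_l": np.round(np.exp(0.4 + 1.0 * crp_z), 2),
        "bmi": np.round(c["bmi"], 1),
        "on_tg_treatment": on_tg_rx,
        "on_hdl_treatment": on_hdl_rx,
        "on_htn_treatment": on_htn,
        "htn_diagnosis": htn_dx,
        "on_glucose_treatment": on_glu_rx,
    })
    clinical["total_chol_mg_dl"] = np.round(
        clinical["ldl_mg_dl"] + clinical["hdl_mg_dl"]
        + clinical["triglycerides_mg_dl"] / 5.0, 1)
    clinical["homa_ir"] = np.round(
        clinical["glucose_mg_dl"] * clinical["insulin_uiu_ml"] / 405.0, 3)
    return clinical, delta


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def generate(config: GeneratorConfig) -> CohortBundle:
    """Draw a complete two-wave cohort bundle from the configured conditions."""
    rng = np.random.default_rng(config.seed)
    n = config.n_train + config.n_test
    ids = pd.Index([f"S{i:05d}" for i in range(n)], name="subject_id")
    wave = np.array(["core"] * config.n_train + ["refresher"] * config.n_test)

    sex = np.where(rng.random(n) < 0.455, "male", "female")
    demo = pd.DataFrame({
        "wave": wave,
        "sex": sex,
        "race": np.where(rng.random(n) < 0.75, "white", "non_white"),
        "age_years": np.round(rng.uniform(35, 90, n), 1),
        "education": rng.choice(["hs_or_less", "college", "postgraduate"], n,
                                p=[0.24, 0.52, 0.24]),
        "smoking": rng.choice(["never", "former", "current"], n, p=[0.45, 0.35, 0.20]),
        "physical_activity": (rng.random(n) < 0.6).astype(int),
    }, index=ids)

    D = rng.standard_normal(n)
    diet, planted_bands = _generate_diet(rng, D, sex == "male", config.diet_missing_rate)
    diet.index = ids

    scores, _ = score_hei_table(diet)
    hei = scores["hei_total"].reindex(ids)
    hei_complete = hei.dropna()
    hei_z = ((hei_complete - hei_complete.mean()) / hei_complete.std(ddof=0)).reindex(ids)
    lipids, truth_loadings, r_h = _generate_lipids(rng, D, hei_z.to_numpy(), config)
    lipids = LipidMatrix(lipids.values.set_index(ids), lipids.below_lod.set_index(ids),
                         lipids.species_meta)

    clinical, delta = _generate_clinical(
        rng, D, demo, config.biomarker_effects, config.mets_target_prevalence)
    clinical.index = ids

    truth = {
        "latent": pd.DataFrame({"diet_quality": D}, index=ids),
        "loadings": truth_loadings,
        "meta": {
            "config": {k: v for k, v in asdict(config).items() if k != "biomarker_effects"},
            "biomarker_effects": config.biomarker_effects,
            "hei_latent_correlation": r_h,
            "mets_shift": delta,
        },
    }
    return CohortBundle(demographics=demo, diet=diet, lipids=lipids,
                        clinical=clinical, ground_truth=truth)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_FILES = {
    "demographics": "demographics.csv",
    "diet": "diet.csv",
    "clinical": "clinical.csv",
    "lipid_values": "lipids.csv",
    "lipid_mask": "lipid_lod_mask.csv",
    "species_meta": "species_meta.csv",
}


def write_bundle(bundle: CohortBundle, directory) -> None:
    """Write all tables as CSV; ground truth goes under ``truth/``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bundle.demographics.to_csv(d / _FILES["demographics"])
    bundle.diet.to_csv(d / _FILES["diet"])
    bundle.clinical.to_csv(d / _FILES["clinical"])
    bundle.lipids.values.to_csv(d / _FILES["lipid_values"])
    bundle.lipids.below_lod.to_csv(d / _FILES["lipid_mask"])
    bundle.lipids.species_meta.to_csv(d / _FILES["species_meta"])
    t = d / "truth"
    t.mkdir(exist_ok=True)
    bundle.ground_truth["latent"].to_csv(t / "latent.csv")
    bundle.ground_truth["loadings"].to_csv(t / "loadings.csv")
    (t / "meta.json").write_text(json.dumps(bundle.ground_truth["meta"], indent=2))


def read_bundle(directory) -> CohortBundle:
    """Round-trip reader for :func:`write_bundle` output."""
    d = Path(directory)
    for key, fname in _FILES.items():
        if not (d / fname).exists():
            raise FileNotFoundError(f"bundle file missing: {fname}")
    demo = pd.read_csv(d / _FILES["demographics"], index_col="subject_id")
    diet = pd.read_csv(d / _FILES["diet"], index_col="subject_id")
    clinical = pd.read_csv(d / _FILES["clinical"], index_col="subject_id")
    values = pd.read_csv(d / _FILES["lipid_values"], index_col="subject_id")
    mask = pd.read_csv(d / _FILES["lipid_mask"], index_col="subject_id")
    meta = pd.read_csv(d / _FILES["species_meta"], index_col="species")
    truth = {}
    if (d / "truth" / "latent.csv").exists():
        truth = {
            "latent": pd.read_csv(d / "truth" / "latent.csv", index_col="subject_id"),
            "loadings": pd.read_csv(d / "truth" / "loadings.csv", index_col="species"),
            "meta": json.loads((d / "truth" / "meta.json").read_text()),
        }
    return CohortBundle(demographics=demo, diet=diet,
                        lipids=LipidMatrix(values, mask.astype(bool), meta),
                        clinical=clinical, ground_truth=truth)
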