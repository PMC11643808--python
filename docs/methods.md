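# Methods notes

This note records the modelling assumptions, parameter choices, and numerical
conventions behind `dietsig`, and what the synthetic-data tests do and do not
demonstrate.

## Diet-quality index

The index sums ten component scores (0/0.5/1; fruits-and-vegetables
0/0.5/1/2) over recommended-intake bands. Band edges printed as integer
serving counts leave real-valued intakes ambiguous (e.g. 2.5 servings
between the "1–2" and "3–4" bands); we bin count-style items by flooring to
whole servings before band lookup, since the source questionnaires elicit
serving counts. Items whose bands are genuine real intervals (oily fish,
fast food, fermented dairy) are compared directly. Two further conventions:

* **Lean meat.** The printed minimal band ("none") overlaps the
  intermediate band ("0–2") at zero. We resolve it as: exactly 0 → 0
  points, (0, 2] → 0.5, ≥ 3 → 1.
* **Alcohol.** "Nondrinker" (zero frequency or zero quantity) is minimal,
  as is drinking over the sex-specific limit (> 2 drinks/day for men,
  > 1 for women, limits inclusive). Within-limit drinking scores 1 at
  ≥ 3 days/week and 0.5 below; quantities under one drink/day count as
  within-limit for both sexes.

Missing answers make a component unscorable and exclude the subject from
index-dependent stages (complete-case, matching the source analyses); no
imputation is attempted.

## Lipid QC and standardization

Species are retained only when **strictly less than 20%** of their
measurements fall below the limit of detection, so a species at exactly 20%
is dropped. Censored cells of retained species have no stated convention in
the source analyses; the default (`rank_low`) assigns them a common value
below the observed column minimum so they share the lowest average rank
under the Blom transform, which uses the classical constants
z = Φ⁻¹((r − 3/8)/(n + ¼)) with average ranks for ties. `half_min` and
`zero` imputation are available. The transform is computed on the pooled
waves by default (it precedes the train/test split in the analysis order);
per-wave transformation is possible by filtering before QC. An
all-constant column degenerates to all-zero scores with a warning.

## Signature

λ is selected by 10-fold cross-validation minimizing MSE (`cv_min`) on the
training wave with seed-controlled folds; `cv_1se` and fixed λ are
available. Predictors enter pre-standardized by Blom with no internal
re-standardization. The signature score deliberately excludes the
intercept — it is a pure weighted sum of selected species — while the
intercept is retained in the model object for mean-level prediction.

Leave-one-out training scores hold λ fixed across the n refits (selected
once on the full training wave), keeping refits comparable; whether
training-wave scores in the source analyses reselected λ per fit is
unknowable, so the fixed-λ choice is flagged as an interpretation. The
refits use a covariance-updating coordinate-descent solver: the Gram matrix
X′X and moments X′y are computed once and downdated per left-out subject
(O(p²) per refit), with warm starts, active-set sweeps, and a full KKT
check; the test suite verifies exact agreement (10⁻⁶) with an independent
LASSO implementation, per-subject.

**Empty-signature convention.** If the training fit selects zero species,
the signature does not exist and every score is zero. Running per-subject
LOO refits regardless would manufacture tiny scores that are systematically
anti-correlated with the outcome (the classic negative bias of
cross-validated predictions under the null, r ≈ −0.3 in our null
simulations) and would misrepresent "no signature" as a negative
association. Degenerate zero-variance score vectors are reported as r = 0.

## Metabolic syndrome and cardiovascular risk

ATP III criteria use the printed inequalities verbatim (waist strictly
> 102/88 cm; triglycerides ≥ 150; HDL < 40/50; BP ≥ 130 or ≥ 85;
glucose ≥ 100), with medication overrides; the hypertension override
requires medication **and** a prior diagnosis. Missing medication flags
default to false (conservative toward non-disease) with a warning.

The pooled-cohort-equation constants (four race–sex groups: coefficients,
group means, baseline survivals) are embedded as an inspectable table in
`cvd_risk.py`. Eligibility windows are inclusive at both ends ("between X
and Y" read as clinical calculators do), and boundary subjects are visible
in the exclusion log. Subjects outside the two published race groups map to
the "white or other" coefficient set, as the equations recommend. Diabetes,
when no explicit diagnosis is carried, is derived from glucose-lowering
treatment or HbA1c ≥ 6.5%. Risk normalization defaults to rank-based
inverse-normal scores of the risk distribution because the source
description ("inverse cumulative distribution function") is ambiguous;
elementwise Φ⁻¹(risk) is available as `direct_quantile` and outputs are
labelled with the method used.

## Association models

Exposure and continuous outcomes are z-scored on the analysis sample, so
linear coefficients are standardized and comparable across biomarkers (the
scale on which the source tables report). Model tiers nest structurally
(I ⊂ II ⊂ III); BMI is never adjusted for itself (tier I only). Physical
activity enters only the logistic models, as printed. Education is encoded
as two dummies against a postgraduate reference, smoking as never/former
against current, wave as a core-vs-refresher indicator. The
cardiovascular-risk ladder additionally emits an odds-ratio-scale view
(exp of the standardized coefficient) clearly flagged `or_scale`, because
the source reports that association as an OR while describing a linear
model; the linear coefficient is primary. All fits are complete-case; no
multiple-testing correction is applied (matching the source; an FDR column
can be added downstream).

## Synthetic cohort generator

All effects run through a single latent diet-quality factor D ~ N(0,1):
the analysis consumes only the index total, so one factor suffices for
testability.

* **Questionnaire.** Component bands are assigned by thresholding
  u_j = √w·D + √(1−w)·e_j at fixed quantiles, then a serving value is drawn
  inside the chosen band. The quantiles and w = 0.80 were calibrated once
  by Monte-Carlo so the scored index has mean ≈ 5.79, SD ≈ 1.55 and
  correlation ≈ 0.92 with D. An exact SD of 1.5 together with correlation
  ≥ 0.9 is not jointly attainable for a 23-level sum of 10 step functions —
  the discreteness/nonlinearity caps the Pearson correlation — so the SD
  target was relaxed slightly in favour of coupling margin, and the band
  margins are compressed toward the intermediate bands relative to real
  survey marginals. That stylization is a known limitation: passing tests
  demonstrate pipeline correctness on cohorts with this structure, not
  robustness to realistic questionnaire marginals.
* **Lipids.** A planted subset of species (default 57 of 400) loads on D
  with geometrically decaying loadings (ratio 0.65, so a handful of species
  dominate, as in observed diet signatures) and random signs; the scale is
  solved by bisection so the *population* correlation between the optimal
  linear combination of signal species and the scored index equals the
  configured coupling ρ (feasible only for ρ below the index–factor
  correlation; otherwise the generator raises with the feasible bound).
  Concentrations are species-specific lognormal transforms of the latent
  z-scores (rank methods are invariant to this). The lowest cells per
  species are flagged below-LOD (default 2%); a subset of noise-only
  species is censored heavily (25–60%) so the QC filter has real work.
  Planted species are never heavily censored.
* **Clinical variables.** Biomarkers are linear (or log-linear, for the
  right-skewed markers) in D, BMI, age and sex with the documented sign
  structure (HDL-c positive; insulin, HOMA-IR, IL-6, CRP, BMI negative;
  LDL-c near zero); HOMA-IR is computed as glucose×insulin/405. The five
  syndrome axes share a common offset solved by bisection on the generated
  sample so the classified prevalence matches the target (default 37%).
  Blood pressure is nearly diet-independent by design, mirroring the source
  finding that hypertension was not associated with the index.
* **Demographics.** Sex ≈ 45/55, ≈ 75% white, three education bands, ages
  uniform 35–90, two waves (default 1200 train / 850 test).

Ground truth (latent factor, loadings, planted effects) is written to a
`truth/` sidecar the pipeline never reads.

## Problem sizes and numerics

The recovery checks run the full pipeline at the default cohort scale
(1200 + 850 subjects, 400 species) over 20 seeds per coupling in
{0, 0.2, 0.4}; the observed combined correlations track the planted values
to within ±0.05 in the mean, with residual attenuation (~0.02–0.04) from
finite-sample estimation of the lipid combination. Coordinate-descent
convergence uses a scaled max-update tolerance of 1e-9 with a KKT slack of
1e-10; collinearity is detected by rank-revealing QR on z-scored design
columns; logistic separation is flagged when Wald standard errors blow up.

## Known limitations

* The generator's single-factor structure cannot probe confounding between
  individual foods and specific lipid classes, nor class-specific
  covariance among species.
* Questionnaire marginals are stylized (see above); absolute agreement
  with real cohort index distributions is limited to mean/SD targets.
* Lipid concentrations carry no real units; only ranks are meaningful.
* The risk equations are implemented exactly as published, without
  recalibration to contemporary event rates.
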