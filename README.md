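# dietsig

Diet quality is usually measured with food-frequency questionnaires, but
self-report is noisy and misses the metabolic response to what people
actually eat. `dietsig` implements an analysis pipeline for two-wave cohort
studies that (1) scores diet quality with a 10-component healthy eating
index, (2) derives a serum **lipidomic signature** of that index by
penalized regression, and (3) relates the signature to metabolic syndrome,
cardiometabolic biomarkers, and estimated 10-year cardiovascular risk.
It is aimed at nutritional-epidemiology analysts who want each of those
stages as tested, scriptable components, plus a synthetic-cohort generator
with planted effects so the whole pipeline can be validated end to end
without restricted cohort data.

## The model in brief

**Healthy eating index (0–11).** Ten food components (fruits/vegetables,
whole grains, oily fish, lean meat, non-meat protein, sugared beverages,
high-fat meat, fast food, fermented dairy, alcohol) each score 0 / 0.5 / 1
against recommended-intake bands; fruits-and-vegetables is double-weighted
(0/0.5/1/2), giving a total H ∈ [0, 11].

**Lipid QC.** Species with ≥ 20% of measurements below the limit of
detection are dropped; every retained species is standardized by Blom's
rank-based inverse-normal transform
z_i = Φ⁻¹((r_i − 3/8)/(n + 1/4)).

**Signature.** On the training wave, H is regressed on the standardized
panel X with the LASSO, min_{β₀,β} (2n)⁻¹‖H − β₀ − Xβ‖² + λ‖β‖₁,
λ chosen by 10-fold cross-validation. A subject's signature score is the
intercept-free weighted sum Σ_s β_s x_s over selected species. Training-wave
scores are computed leave-one-out (subject *i* scored by a model refitted
without *i* at the same λ) so the reported training correlation is honest;
testing-wave subjects are scored with the frozen model. Agreement with H is
summarized by Pearson's r.

**Clinical endpoints.** Metabolic syndrome is classified by the updated
ATP III rule (≥ 3 of 5 criteria, with medication overrides); 10-year ASCVD
risk uses the 2013 pooled cohort equations
(risk = 1 − S₀^exp(Σβ·x − mean)) inside their eligibility window
(age 40–79, TC 130–320, HDL 20–100, SBP 90–200), and risks are normalized to
a z-scale. Associations are estimated with three nested models —
I: wave + age + sex + race; II: + BMI; III: + diet index — as standardized
linear coefficients, and with logistic models of the syndrome on the index
(odds ratio per index point).

## Worked example

Run the full pipeline on a simulated 1200 + 850 subject two-wave cohort with
400 lipid species, 57 of which load on the latent diet-quality factor at a
planted signature–index coupling of 0.4:

```python
from dietsig.pipeline import PipelineConfig, run_all

cfg = PipelineConfig(seed=17, out_dir="demo_run",
                     simulate={"n_train": 1200, "n_test": 850, "n_lipids": 400,
                               "n_signal_lipids": 57, "diet_lipid_coupling": 0.4})
run_all(cfg)
```

The manifest (`demo_run/manifest.json`) from that exact run reports:

```
stages: {'input': 2050, 'hei_scored': 2050, 'species_retained': 380,
         'signature_scored': 2050, 'mets_classified': 2050,
         'risk_eligible': 1371, 'association_fits': 37}
lambda: 0.0713  n_selected: 35
train:    r=0.329  p=1.2e-31  n=1200
test:     r=0.349  p=8.4e-26  n=850
combined: r=0.338  p=8.4e-56  n=2050
```

Reading this: 20 of 400 species failed the detection-limit filter; the
cross-validated LASSO kept 35 species; the leave-one-out training
correlation (0.33) and the out-of-sample testing correlation (0.35) both
sit near the planted coupling of 0.4 (attenuated by estimation noise), and
1371 of 2050 subjects fell inside the risk-calculator window. The
association table (`associations.csv`) shows the expected ladder behaviour,
e.g. HDL-c: +0.123 (model I) → +0.097 (model II, BMI-adjusted) → +0.028
(model III, index-adjusted), the tier-III attenuation reflecting that the
planted biomarker effects run entirely through diet quality.

Each stage is also exposed as a CLI:
`dietsig simulate | score-hei | qc | fit-signature | score-signature | mets |
risk | validate | run-all` (see `dietsig --help`).

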