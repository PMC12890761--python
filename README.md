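# dkdrisk

A 36-month diabetic kidney disease (DKD) risk toolkit for clinical-model
researchers. It implements a literature-informed risk framework end to end:
a proportional-hazards risk engine whose coefficients come from published
external studies rather than a local fit, Bayesian literature-prior
imputation of covariates that are 100% missing in routine registries, a
stacked binary+survival machine-learning ensemble with isotonic
calibration, and a survival-aware evaluation / fairness / stability suite.
Because registry data of this kind is not publicly deposited, the package
ships a first-class synthetic cohort generator that reproduces the
registry's marginal structure, so every stage of the pipeline is testable
and reproducible at desk scale.

## The model

**Risk engine.** Each patient gets a log-hazard linear predictor

```
lp = Σ_k  β_k · t_k(x_k)        β_k = log hazard ratio from the literature
```

with transforms such as age/10 (HR 1.16 per decade), (ref − eGFR)/10
(HR 1.24 per 10 mL/min decrease, referenced to the CKD-stage bracket
midpoint), log₂(ACR/10) (HR 1.30), HbA1c − 7 (HR 1.13), and indicators for
smoking (1.35), family history of CKD (2.04), retinopathy grade
(2.9/5.8/10.2/16.6), SGLT2-inhibitor use (0.61), and other protective
therapies. The 36-month risk uses the continuous-rate survival form

```
risk36 = 1 − exp(−36 · h_stage · exp(lp))
```

with monthly base hazards 0.00048 / 0.0013 / 0.0030 / 0.0070 / 0.016 for
no CKD through stage 4, risk categories `<5% / 5–15% / 15–30% / >30%`, and
a complexity-adjusted uncertainty half-width `0.05 + 0.01·n_features`.

**Imputation.** Observed variables below 40% missingness get median fills
plus missing-indicator flags. Literature-informed variables (family
history, chronic NSAID use, deprivation quintile, retinopathy grade,
medication exposures) are drawn by chained sampling from their literature
priors — 20 chains, 10 burn-in sweeps, Gelman–Rubin R̂ ≤ 1.01 required —
and released as 20 completed datasets.

**Ensemble.** A gradient-boosted binary classifier (patients with
determinable 36-month status, class-weighted by the negative:positive
ratio) is stacked with a boosted proportional-hazards survival learner
(all patients) on the logit scale:

```
P = σ(0.64·logit(P_binary) + 0.36·logit(P_survival))
```

with optional L2-penalised meta-learning (α = 0.01) of the weights and
isotonic calibration fitted on the validation split of a patient-level
temporal split (≈70/15/15 by index date).

**Evaluation.** IPCW time-dependent AUROC and Uno's C (both verified
against brute-force weighted-pair enumeration), time-dependent Brier and
AUPRC, decile calibration against Kaplan–Meier observed risk with a
cloglog calibration slope/intercept, decision curves with
`NB = TP/n − (FP/n)·pt/(1−pt)`, BCa bootstrap optimism, subgroup fairness
audit (flags at |Δ-AUROC| > 0.03 or slope outside 0.8–1.2), individual
prediction-interval stability, and drift triggers (AUROC drop > 0.05,
slope outside 0.85–1.15).

## Worked example

```bash
python examples/02_risk_engine.py
```

```
36-month kidney outcome risk: 27.7%
category:                     high
uncertainty half-width:       25% of the point risk
interval:                     [20.8%, 34.7%]
top log-hazard contributions:
  acr                    +0.594
  sglt2i                 -0.494
  diabetes_duration      +0.267
  medication_compliance  +0.262
  ace_arb                -0.261
```

A 67-year-old man with stage-3a kidney function (eGFR 55), ACR 48 mg/g and
14 years of diabetes has a 27.7% predicted 36-month risk — in the `high`
category (15–30%). Albuminuria (+0.594 on the log-hazard scale) is the
largest single driver; his SGLT2-inhibitor and ACE/ARB therapy pull the
hazard down. The interval reflects the engine's feature-count-based
uncertainty rule, not a sampling CI.

The other scripts in `examples/` walk through cohort generation,
literature-prior imputation, ensemble fitting, the evaluation suite,
prior-scaling sensitivity, and outcome adjudication — each prints its
numbers with a line on what they mean.

## Command line

A thin CLI wraps the library:

```bash
dkdrisk simulate --n 20000 --seed 42 --out cohort.csv
dkdrisk impute --in cohort.csv --chains 20 --burn-in 10 --seed 42 --out imputed/
dkdrisk predict --in cohort.csv --out risks.csv
dkdrisk evaluate --preds risks.csv --cohort cohort.csv --out report.json
dkdrisk audit --preds risks.csv --cohort cohort.csv --out fairness.csv
dkdrisk sensitivity --n 20000 --seed 42 --out sensitivity.json
```

Every subcommand writes a JSON manifest beside its output; exit codes are
0 (success), 2 (validation error), 1 (other failure). The cohort CSV
schema is one row per patient: `patient_id, index_date (ISO month), age,
sex, ethnicity, bmi, waist_circumference, sbp, dbp, egfr, acr, hba1c,
phosphorus, fgf23, diabetes_duration, smoking, hypertension, cvd,
medication_compliance, followup_months, event, censor_reason`, with
missing values as empty cells; `fixtures/cohort_example.csv` shows five
hand-written records.

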