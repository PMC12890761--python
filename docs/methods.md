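# Methods

This note documents the modelling choices behind `dkdrisk`: the risk
model, the synthetic registry generator, the literature-prior imputation,
the ensemble and evaluation machinery, and the places where the design was
genuinely open and a choice had to be made.

## The risk model

The engine is a proportional-hazards calculator with externally sourced
coefficients. Survival uses the continuous-rate form
`risk36 = 1 − exp(−36 · h_stage · exp(lp))`, reading the published monthly
base hazards as rates; the discrete-compounding alternative
`1 − (1 − h)^36` differs by under 0.1% at these hazard magnitudes. The
form is isolated in one place so discrete compounding could be swapped in.

eGFR influences risk through two channels that must not double count: the
CKD-stage base hazard (between stages) and the continuous per-10-mL/min
effect (HR 1.24). The continuous effect is therefore taken **relative to a
stage-specific reference** — the bracket midpoints 95 / 75 / 52 / 37 / 22
mL/min — so it acts within a stage while the base hazard carries the
between-stage gradient. Both published constants stay live.

Other transform anchors: age reference 60 y; HbA1c 7%; BMI 25 kg/m²; SBP
120 mmHg; diabetes duration 0 y; medication compliance 10/10 (effect per
2-point decrease); waist circumference 100 cm (a round value near the
cohort median; no reference is published). ACR enters as log₂(ACR/10 mg/g)
with a floor at 1 mg/g — "per log₂ unit" needs an anchor and 10 mg/g is
the upper normal bound. Missing features contribute zero to the linear
predictor and are excluded from the supplied-feature count that drives the
uncertainty rule `0.05 + 0.01·n_supplied` (multiplicative half-width).
Category bins are left-closed (a 15.0% risk is `high`), consistent with
the ">30%" label of the top bin.

Clinical-gain importance is the mean absolute log-hazard contribution per
feature, normalised to 100%. Because the engine routes eGFR through the
stage hazard as well, the cohort-centred stage log-hazard offset is
credited to eGFR; without this the attribution would claim eGFR barely
matters while the stage term silently carries it. For black-box learners
the analogous quantity is a permutation attribution (mean |Δ prediction|
under feature shuffling).

## The synthetic registry generator

The generator emulates a tertiary-care type-2-diabetes registry at the
level the pipeline needs: covariate marginals, a proportional-hazards
event process, competing risks, administrative censoring, and realistic
missingness. What it deliberately does **not** emulate: longitudinal
visit-level trajectories, correlation structure beyond what the risk model
uses (covariates are drawn independently given CKD stage), measurement
error, or informative (outcome-dependent) missingness. Passing tests on
this cohort therefore demonstrate internal consistency of the methods, not
performance on real registry data.

Key construction choices:

- **CKD stage first, eGFR within stage.** Stage is categorical
  (55.2 / 34.6 / 7.0 / 2.3 / 0.9%), eGFR uniform within the stage bracket
  (90–120 for no CKD). This pins both the stage mix and an overall median
  near 92 mL/min.
- **Right-skewed labs.** ACR's published mean/SD (92 ± 420) and
  median/IQR (17, 8–32) cannot both hold for any simple family; a
  log-normal is matched to the median/IQR, the robust pair. FGF-23 is
  treated the same way.
- **Unpublished marginals chosen once:** medication compliance
  ~N(8, 2) truncated to 0–10; smoking never/former/current 80/8/12%.
  Prescription prevalences for the protective therapies are needed by the
  generator and imputer but largely unpublished; defaults are SGLT2i 30%
  (the one value derivable from the source fairness table), ACE/ARB 50%
  (hypertension prevalence is 67%), statin 60%, GLP-1 RA 15%, finerenone
  5% (recently approved agent).
- **Event times** are exponential with monthly rate
  `h_stage · exp(lp_true) · m`, where `lp_true` uses the engine transforms
  on the *true* (pre-masking) covariates plus the literature-informed
  variables, and the continuous eGFR effect is off by default (stage
  carries it; a single-stage mode activates it for recovery checks). The
  scalar `m` is solved by bisection so the realised negative:positive
  ratio at 36 months is 9.5; it is logged with the cohort.
- **Censoring.** Death/transplant arrive at 0.2%/month and are recorded
  as censoring. Administrative censoring time is uniform on a window
  `[L, 72]` months with `L` solved so that exactly the target fraction
  (10.1%) is censored short of the horizon. The censoring time is drawn
  independently of the enrolment month: coupling it deterministically to
  the index date would concentrate all censoring in the latest temporal
  split and distort its outcome prevalence several-fold.
- **Whole-month storage.** Follow-up is stored in integer months: event
  times round up (an event inside month k is recorded at k), censoring
  times round down (only completed months are observed). The tuning
  targets are computed on the recorded months, so the stored cohort — not
  an internal continuous version — hits 10.1% and 9.5.
- **Ground truth retained.** `true_*` columns keep the unmasked
  covariates, the literature-variable truths, the generating linear
  predictor and the generating 36-month risk, enabling
  simulation-and-refit recovery (Cox fits recover each generating HR
  within Monte-Carlo error at n = 50,000) and calibration
  self-consistency (scoring with `true_risk36` gives slope ≈ 1).

## Literature-prior imputation

Observed variables with under 40% missingness get median fills plus 0/1
missing-indicator columns; variables at or above the threshold (waist
circumference at 43.8%) are left to the learners, which handle missing
values natively. An entirely missing observed variable is routed to the
literature path with a warning.

Literature-informed variables are sampled per chain, per sweep: first the
variable's parameters are drawn from the prior — the prevalence target
from a Beta/Dirichlet whose spread matches the prior's prevalence
uncertainty (±1 pp by default), conditioning coefficients from normals
centred on the registry associations — then patient values are drawn
conditional on observed covariates. The intercept is re-solved each sweep
(Newton iteration on the cohort-mean probability; exponential-tilting
fixed point for ordinal grades) so the marginal prevalence always tracks
the drawn target: chained sampling cannot drift away from the literature
marginals, which is the fidelity property the framework promises (pooled
prevalences within 1 pp of the priors).

Conditioning is weak and optional. The shipped registry conditions
retinopathy grade on HbA1c and diabetes duration, chronic NSAID use on
age, and SGLT2i use on HbA1c (0.10–0.12 per SD, plausible directions);
all other variables impute independently. Conditioning coefficients scale
with the prior-sensitivity factor, so flat priors (scale 0) reproduce
fully independent imputation. Prior scaling itself acts on the log-HR
scale — shrinkage toward the null means toward HR 1 — and is
multiplicative (scaling by a then b equals scaling by a·b).

Each chain runs `burn_in + monitor` sweeps (defaults 10 + 60); the final
sweep is released, one completed dataset per chain (20 chains → 20
datasets). The monitored Gelman–Rubin quantity per variable is the
per-sweep prevalence (binary) or mean grade (ordinal), using the standard
potential-scale-reduction formula; zero within-chain variance is reported
as R̂ = 1 with a degenerate flag. The 60-sweep monitor window is a
diagnostic-resolution choice: R̂'s sampling noise scales roughly as
(F − 1)/2N for an F-statistic with chain degrees of freedom, so N = 60
puts 3σ of estimator noise safely below the 0.01 convergence criterion
that the framework enforces.

The posterior-predictive check sums squared standardised deviations of
per-dataset prevalences from their priors and compares against
prior-replicated cohorts of the same size; the p-value is the fraction of
replicates at least as discrepant. By construction it is approximately
uniform when the imputations really come from the priors.

Point predictions pool across completed datasets by plain averaging;
interval pooling, when needed, applies the standard combination rule on
the logit scale.

## Ensemble and splitting

The temporal split assigns patients by index date alone — three closed
month-windows, by default placed at the 70/15/15 date quantiles — making
patient leakage across splits structurally impossible (and duplicate ids
are rejected at cohort construction). The binary censoring policy drops
administratively censored patients short of the horizon (status
indeterminate); follow-up of exactly 36 months counts as complete; death
and transplant before the horizon are retained as non-events. The
survival formulation keeps everyone.

Base learners are pluggable. The reference binary learner is LightGBM
with `scale_pos_weight` recomputed per completed dataset from the training
split's class ratio; the reference survival learner is gradient boosting
on the Cox partial likelihood (XGBoost's `survival:cox`) with the Breslow
baseline cumulative hazard computed in-package to convert relative hazards
into 36-month probabilities. A small random search (default 10 trials)
over the documented space (num_leaves 7–127, depth 2–8, learning rate
0.01–0.30, min leaf 10–100) stands in for the full 600-evaluation search,
which is configuration, not method.

The combiner is exact: `σ(0.64·logit(p_bin) + 0.36·logit(p_surv))` with
inputs clipped to [1e-6, 1−1e-6]; learned mode fits an L2-penalised
logistic meta-learner (α = 0.01) on the two base logits over the
validation split and adds an intercept. Isotonic calibration is fitted on
the *stacked* validation output (calibrating base learners individually
and then stacking would destroy the fixed-weight interpretation); with
fewer than 10 validation points the calibrator degrades to the identity
with a warning. Test-window patients never inform calibration.

## Evaluation

All censoring-aware metrics share one censoring-survival estimator: a
Kaplan–Meier fit to the censoring indicator, evaluated left-continuously,
ties broken event-before-censor. IPCW AUROC is the cumulative/dynamic
version (cases weighted 1/G(T−), horizon survivors 1/G(36)); the
censoring-robust concordance weights usable pairs by 1/G(T_i)². Both are
verified in the tests against exhaustive weighted-pair enumeration to
1e-10 and against the independent scikit-survival implementations, and
both reduce exactly to their unweighted forms without censoring.

Calibration reports deciles of predicted risk against Kaplan–Meier
observed risk with Greenwood intervals; the slope is the coefficient of a
Cox regression on cloglog(p̂) (survival-appropriate scale) and the
intercept compares overall observed and mean predicted risk on the same
scale. Subgroup calibration inside the fairness audit uses the logistic
analogue on 36-month binary outcomes. Decision curves use the standard
net-benefit formula with IPCW-weighted true/false positives;
"events prevented per 1000 screened" is reported as
`1000 × (NB_model − NB_treat-all)`, the standard decision-curve summary of
an ambiguous verbal definition. Fairness comparisons are flagged by
threshold only (|Δ-AUROC| > 0.03, slope outside 0.8–1.2 versus the largest
subgroup as reference), with no multiplicity adjustment — matching the
framework's specification. Drift triggers fire when AUROC drops by more
than 0.05 or the slope leaves 0.85–1.15; a drop of exactly 0.05 does not
fire.

Bootstrap optimism uses patient-level resampling with refits; the BCa
interval takes its acceleration from a (subsampled) jackknife of the
evaluation under the original model — a documented approximation that
avoids n refits. Stability intervals refit on bootstrap resamples and
summarise each patient's 2.5–97.5 percentile prediction spread in
percentage points, banded at <5 / 5–10 / >10.

## Problem sizes and determinism

Default analysis sizes: cohorts of 20,000 for imputation, censoring and
sensitivity analyses; 50,000 for parameter-recovery refits; 20 imputation
chains with the first 5 used for ensemble fitting in the sensitivity
pipeline (averaging predictions across them). These sizes put Monte-Carlo
error comfortably inside every tolerance the package asserts while keeping
any single analysis in the minutes range on one CPU. Every stochastic
operation takes an explicit seed (default 42); generation, imputation and
fitting are bit-reproducible for fixed library versions.

## Known limitations

- Imputed literature variables carry population-level, not patient-level,
  information: on synthetic data they are noise features for the
  discriminative learners, so ensemble AUROC reflects observed covariates
  only. This mirrors the structural situation of any 100%-missing
  imputation and is why the prior-sensitivity spread is small.
- The generator's independence assumptions (covariates within stage,
  censoring vs enrolment) make its cohorts cleaner than real registries;
  fairness audits on it cannot surface real-world subgroup pathologies.
- The deployed-engine predictions are intentionally *not* refit to the
  generator; when scoring raw cohorts without imputed literature
  variables, the engine underestimates hazard dispersion and its
  calibration slope on synthetic cohorts falls below 1.
- The combined protective-therapy effect is represented by its components
  only; no combined hazard ratio is stored or reproduced.
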