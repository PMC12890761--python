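"""Temporal splitting, base learners, the stacked combiner, and
isotonic calibration.

The production model stacks a gradient-boosted binary classifier
(trained on patients with determinable 36-month status) with a boosted
proportional-hazards survival learner (trained on everyone, censoring
handled by partial likelihood).  Base predictions are combined on the
logit scale:

    P_ensemble = sigma(w_bin * logit(P_bin) + w_surv * logit(P_surv))

with fixed production weights (0.64, 0.36) or weights learned by an
L2-penalised logistic meta-learner on the validation split.  Isotonic
calibration is fitted on validation-split stacked output only — test
patients never inform calibration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression

from ._errors import ConfigError, DomainError, IntegrityError
from .core_types import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "SplitAssignment",
    "EnsembleSpec",
    "EnsembleModel",
    "temporal_split",
    "censoring_filter",
    "binary_label36",
    "stack_predict",
    "fit_meta",
    "isotonic_calibrate",
    "IdentityCalibrator",
    "feature_matrix",
    "fit_binary_learner",
    "fit_survival_learner",
    "tune_binary_learner",
    "fit_ensemble",
]

_CLIP = 1e-6

HORIZON = 36.0

_SEARCH_SPACE = {
    "num_leaves": (7, 127),
    "max_depth": (2, 8),
    "learning_rate": (0.01, 0.30),
    "min_child_samples": (10, 100),
}


# ---------------------------------------------------------------------------
# temporal split

@dataclass(frozen=True)
class SplitAssignment:
    """Patient-level temporal cohort assignment (a function of index_date)."""

    assignment: pd.Series  # patient_id -> {train, validation, test}
    windows: tuple[tuple[str, str], ...]
    fractions: dict[str, float]

    def ids(self, split: str) -> pd.Index:
        return self.assignment.index[self.assignment == split]

    def select(self, cohort: Cohort, split: str) -> Cohort:
        mask = cohort.df["patient_id"].isin(self.ids(split))
        return Cohort(cohort.df.loc[mask].reset_index(drop=True), cohort.provenance)


def temporal_split(
    cohort: Cohort,
    windows: Optional[tuple[tuple[str, str], ...]] = None,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> SplitAssignment:
    """Assign each patient to train/validation/test by index date.

    ``windows`` are three closed ``(start, end)`` intervals of ISO
    months.  When omitted they are built at the cohort's index-date
    quantiles (default 70/15/15).  A patient outside every window is an
    assignment error; the same patient can never land in two splits
    because assignment is a pure function of the index date.
    """
    df = cohort.df
    if df["index_date"].isna().any():
        missing = df.loc[df["index_date"].isna(), "patient_id"].tolist()[:5]
        raise DomainError(f"index_date missing for patients {missing}")
    dates = df["index_date"].astype(str)
    if windows is None:
        qs = np.cumsum(fractions)[:2]
        sorted_dates = dates.sort_values().to_numpy()
        c1 = sorted_dates[min(int(qs[0] * len(dates)), len(dates) - 1)]
        c2 = sorted_dates[min(int(qs[1] * len(dates)), len(dates) - 1)]
        lo, hi = dates.min(), dates.max()
        windows = ((lo, c1), (_next_month(c1), c2), (_next_month(c2), hi))
    labels = ("train", "validation", "test")
    assign = pd.Series(pd.NA, index=pd.Index(df["patient_id"], name="patient_id"), dtype="object")
    for label, (start, end) in zip(labels, windows):
        in_win = (dates >= start) & (dates <= end)
        clash = in_win.to_numpy() & assign.notna().to_numpy()
        if clash.any():
            raise IntegrityError(
                f"windows overlap: patients {df.loc[clash, 'patient_id'].tolist()[:5]} "
                f"fall in multiple windows"
            )
        assign.iloc[np.flatnonzero(in_win.to_numpy())] = label
    if assign.isna().any():
        outside = assign.index[assign.isna()].tolist()[:5]
        raise DomainError(f"patients outside all split windows: {outside}")
    fracs = assign.value_counts(normalize=True).to_dict()
    logger.info("temporal_split fractions: %s", fracs)
    return SplitAssignment(assignment=assign, windows=tuple(windows), fractions=fracs)


def _next_month(ym: str) -> str:
    y, m = int(ym[:4]), int(ym[5:7])
    m += 1
    if m > 12:
        y, m = y + 1, 1
    return f"{y:04d}-{m:02d}"


# ---------------------------------------------------------------------------
# censoring policy

def binary_label36(df: pd.DataFrame, horizon: float = HORIZON) -> pd.Series:
    """36-month binary outcome: event at or before the horizon."""
    return (df["event"].astype(bool)) & (df["followup_months"] <= horizon)


def censoring_filter(cohort: Cohort, mode: str, horizon: float = HORIZON) -> Cohort:
    """Apply the censoring policy of the binary vs survival formulations.

    ``binary`` drops administratively censored patients with follow-up
    short of the horizon and no event (their 36-month status is
    indeterminate); competing-risk censorings are retained and treated
    as non-events.  ``survival`` keeps everyone.
    """
    if mode == "survival":
        return cohort
    if mode != "binary":
        raise ConfigError(f"mode must be 'binary' or 'survival', got {mode!r}")
    df = cohort.df
    drop = (
        (df["censor_reason"] == "administrative")
        & (df["followup_months"] < horizon)
        & (~df["event"].astype(bool))
    )
    return Cohort(df.loc[~drop].reset_index(drop=True), cohort.provenance)


# ---------------------------------------------------------------------------
# stacked combiner

class IdentityCalibrator:
    def predict(self, p):
        return np.asarray(p, dtype=float)


@dataclass
class EnsembleSpec:
    w_binary: float = 0.64
    w_survival: float = 0.36
    intercept: float = 0.0
    meta: str = "fixed_weights"  # or "learned"
    l2_alpha: float = 0.01
    calibrator: object = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.w_binary) and np.isfinite(self.w_survival)):
            raise DomainError("ensemble weights must be finite")


def stack_predict(p_bin, p_surv, spec: EnsembleSpec = EnsembleSpec()):
    """Combine base probabilities on the logit scale with spec weights."""
    pb = np.clip(np.asarray(p_bin, dtype=float), _CLIP, 1 - _CLIP)
    ps = np.clip(np.asarray(p_surv, dtype=float), _CLIP, 1 - _CLIP)
    out = expit(spec.w_binary * logit(pb) + spec.w_survival * logit(ps) + spec.intercept)
    return float(out) if np.isscalar(p_bin) else out


def fit_meta(p_bin, p_surv, outcomes, l2_alpha: float = 0.01) -> EnsembleSpec:
    """Learn combiner weights: L2-penalised logistic regression on the
    two base logits, fitted on validation pairs."""
    y = np.asarray(outcomes, dtype=int)
    if len(np.unique(y)) < 2:
        raise ConfigError("meta-learner needs both outcome classes in the validation set")
    X = np.column_stack([
        logit(np.clip(np.asarray(p_bin, float), _CLIP, 1 - _CLIP)),
        logit(np.clip(np.asarray(p_surv, float), _CLIP, 1 - _CLIP)),
    ])
    lr = LogisticRegression(C=1.0 / l2_alpha, solver="lbfgs", max_iter=1000)
    lr.fit(X, y)
    return EnsembleSpec(
        w_binary=float(lr.coef_[0, 0]),
        w_survival=float(lr.coef_[0, 1]),
        intercept=float(lr.intercept_[0]),
        meta="learned",
        l2_alpha=l2_alpha,
    )


def isotonic_calibrate(preds, outcomes):
    """Fit a monotone non-decreasing calibration map on validation pairs.

    With fewer than 10 points calibration is unidentified: warn and
    return the identity.  Out-of-range inputs are clamped to the fitted
    endpoints.
    """
    p = np.asarray(preds, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(p) < 10:
        warnings.warn("fewer than 10 validation points: identity calibrator returned")
        return IdentityCalibrator()
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(p, y)
    return iso


def apply_calibrator(calibrator, p):
    arr = np.asarray(p, dtype=float)
    out = calibrator.predict(arr.reshape(-1))
    return float(out[0]) if np.isscalar(p) else np.asarray(out)


# ---------------------------------------------------------------------------
# base learners

_OBSERVED_FEATURES = [
    "age", "bmi", "waist_circumference", "sbp", "dbp", "egfr", "acr", "hba1c",
    "phosphorus", "fgf23", "diabetes_duration", "medication_compliance",
]


def feature_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric learner features from a (completed) cohort frame.

    Observed covariates, missing-indicator flags, one-hot smoking/sex,
    comorbidities, and any imputed ``lit_*`` columns.  Remaining NaNs
    (e.g. above-threshold missingness left to the learner) are kept —
    LightGBM handles them natively; the survival learner receives
    median-filled copies.
    """
    cols = {}
    for c in _OBSERVED_FEATURES:
        if c in df.columns:
            cols[c] = df[c].astype(float)
    for c in df.columns:
        if c.endswith("_missing") or c.startswith("lit_"):
            cols[c] = df[c].astype(float)
    if "sex" in df.columns:
        cols["male"] = (df["sex"] == "male").astype(float)
    if "smoking" in df.columns:
        cols["smoking_current"] = (df["smoking"] == "current").astype(float)
        cols["smoking_former"] = (df["smoking"] == "former").astype(float)
    for c in ("hypertension", "cvd"):
        if c in df.columns:
            cols[c] = df[c].astype(float)
    return pd.DataFrame(cols, index=df.index)


def fit_binary_learner(
    X: pd.DataFrame,
    y: np.ndarray,
    params: Optional[dict] = None,
    seed: int = 42,
):
    """Gradient-boosted binary classifier with class-imbalance weighting.

    ``scale_pos_weight`` is the training split's negative:positive
    ratio, recomputed per imputed dataset.
    """
    import lightgbm as lgb

    y = np.asarray(y, dtype=int)
    pos = max(int(y.sum()), 1)
    spw = (len(y) - pos) / pos
    defaults = dict(
        n_estimators=200, num_leaves=31, max_depth=5, learning_rate=0.058,
        min_child_samples=34, verbose=-1,
    )
    defaults.update(params or {})
    model = lgb.LGBMClassifier(
        objective="binary", scale_pos_weight=spw, random_state=seed, **defaults
    )
    model.fit(X, y)
    return model


def tune_binary_learner(
    X_train, y_train, X_valid, y_valid, n_trials: int = 10, seed: int = 42
) -> dict:
    """Small random search over the boosted-classifier space
    (num_leaves 7-127, depth 2-8, learning rate 0.01-0.30, min leaf
    10-100), scored by validation AUROC."""
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(seed)
    best_params, best_score = {}, -np.inf
    for _ in range(n_trials):
        params = {
            "num_leaves": int(rng.integers(*_SEARCH_SPACE["num_leaves"])),
            "max_depth": int(rng.integers(*_SEARCH_SPACE["max_depth"])),
            "learning_rate": float(rng.uniform(*_SEARCH_SPACE["learning_rate"])),
            "min_child_samples": int(rng.integers(*_SEARCH_SPACE["min_child_samples"])),
        }
        model = fit_binary_learner(X_train, y_train, params, seed=seed)
        score = roc_auc_score(y_valid, model.predict_proba(X_valid)[:, 1])
        if score > best_score:
            best_params, best_score = params, score
    logger.info("tuned binary learner AUROC %.4f params %s", best_score, best_params)
    return best_params


def breslow_cumulative_hazard(lp, durations, events, horizon: float) -> float:
    """Breslow baseline cumulative hazard at ``horizon``.

    H0(t) = sum over event times t_i <= t of d_i / sum_{j at risk} exp(lp_j);
    ties share a risk set (Breslow convention).
    """
    lp = np.asarray(lp, dtype=float)
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    order = np.argsort(t)
    t, e, lp = t[order], e[order], lp[order]
    exp_lp = np.exp(lp)
    # risk-set sums: at-risk means duration >= t_i
    rev_cumsum = np.cumsum(exp_lp[::-1])[::-1]
    h0 = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        d = 0
        while j < n and t[j] == t[i]:
            d += int(e[j])
            j += 1
        if d and t[i] <= horizon:
            h0 += d / rev_cumsum[i]
        i = j
    return float(h0)


class SurvivalLearner:
    """Boosted proportional-hazards learner (gradient boosting on the
    Cox partial likelihood) with a Breslow baseline.

    Predicts 36-month event probability as
    ``1 - exp(-H0(36) * exp(lp(x)))`` where lp is the boosted log
    relative hazard, centred on the training mean.
    """

    def __init__(self, n_estimators: int = 200, learning_rate: float = 0.1,
                 max_depth: int = 3, seed: int = 42):
        import xgboost as xgb

        self._model = xgb.XGBRegressor(
            objective="survival:cox", n_estimators=n_estimators,
            learning_rate=learning_rate, max_depth=max_depth,
            subsample=0.8, random_state=seed, tree_method="hist",
        )
        self._h0_horizon = None
        self._lp_center = 0.0

    def fit(self, X: pd.DataFrame, durations, events, horizon: float = HORIZON) -> "SurvivalLearner":
        t = np.asarray(durations, dtype=float)
        e = np.asarray(events, dtype=bool)
        # survival:cox encodes right-censoring as negative labels
        y = np.where(e, t, -t)
        self._model.fit(X.astype(float), y)
        lp = self._model.predict(X.astype(float), output_margin=True)
        self._lp_center = float(np.mean(lp))
        self._h0_horizon = breslow_cumulative_hazard(lp - self._lp_center, t, e, horizon)
        return self

    def predict_risk36(self, X: pd.DataFrame, horizon: float = HORIZON) -> np.ndarray:
        lp = self._model.predict(X.astype(float), output_margin=True) - self._lp_center
        return 1.0 - np.exp(-self._h0_horizon * np.exp(lp))


def fit_survival_learner(X, durations, events, seed: int = 42, **kw) -> SurvivalLearner:
    return SurvivalLearner(seed=seed, **kw).fit(X, durations, events)


# ---------------------------------------------------------------------------
# end-to-end ensemble

@dataclass
class EnsembleModel:
    """Fitted stacked ensemble: binary + survival learners, combiner
    spec, and the validation-fitted isotonic calibrator."""

    binary_learner: object
    survival_learner: SurvivalLearner
    spec: EnsembleSpec
    feature_columns: list[str]

    def _features(self, df: pd.DataFrame) -> pd.DataFrame:
        X = feature_matrix(df)
        return X.reindex(columns=self.feature_columns, fill_value=np.nan)

    def predict_risk36(self, df: pd.DataFrame, calibrated: bool = True) -> np.ndarray:
        X = self._features(df)
        p_bin = self.binary_learner.predict_proba(X)[:, 1]
        p_surv = self.survival_learner.predict_risk36(X)
        p = stack_predict(p_bin, p_surv, self.spec)
        if calibrated and self.spec.calibrator is not None:
            p = apply_calibrator(self.spec.calibrator, p)
        return np.asarray(p)


def fit_ensemble(
    train: Cohort,
    validation: Cohort,
    mode: str = "fixed",
    seed: int = 42,
    binary_params: Optional[dict] = None,
    survival_kw: Optional[dict] = None,
    calibrate: bool = True,
) -> EnsembleModel:
    """Fit the production pipeline on one completed training cohort.

    Binary learner: censoring-filtered 36-month labels with class
    weighting.  Survival learner: all training patients.  Combiner
    weights fixed (0.64/0.36) or learned on the validation split; the
    isotonic calibrator is fitted on validation stacked output.
    """
    bin_cohort = censoring_filter(train, "binary")
    Xb = feature_matrix(bin_cohort.df)
    yb = binary_label36(bin_cohort.df).to_numpy()
    binary = fit_binary_learner(Xb, yb, binary_params, seed=seed)

    Xs = feature_matrix(train.df)
    survival = fit_survival_learner(
        Xs, train.df["followup_months"], train.df["event"], seed=seed, **(survival_kw or {})
    )

    feature_columns = list(Xs.columns)
    model = EnsembleModel(binary, survival, EnsembleSpec(), feature_columns)

    valid_det = censoring_filter(validation, "binary")
    Xv = feature_matrix(valid_det.df).reindex(columns=feature_columns, fill_value=np.nan)
    yv = binary_label36(valid_det.df).to_numpy()
    pb = binary.predict_proba(Xv)[:, 1]
    ps = survival.predict_risk36(Xv)
    if mode == "learned":
        model.spec = fit_meta(pb, ps, yv)
    elif mode != "fixed":
        raise ConfigError(f"mode must be 'fixed' or 'learned', got {mode!r}")
    if calibrate:
        stacked = stack_predict(pb, ps, model.spec)
        model.spec = replace(model.spec, calibrator=isotonic_calibrate(stacked, yv))
    return model
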