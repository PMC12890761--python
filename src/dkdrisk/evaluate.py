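"""Survival-aware evaluation: time-dependent discrimination,
calibration, decision curves, optimism, fairness, stability and drift.

Censoring is handled throughout with inverse probability of censoring
weighting (IPCW): the censoring distribution G is estimated by
Kaplan-Meier on the censoring indicator, evaluated left-continuously,
with ties broken event-before-censor.  Every weighted metric reduces
exactly to its unweighted version when no censoring exists before the
horizon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import norm
from sklearn.metrics import average_precision_score, roc_auc_score

from ._errors import ConfigError, DomainError
from .core_types import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "censoring_survival",
    "ipcw_weights",
    "auroc_ipcw",
    "unos_c",
    "brier36",
    "auprc36",
    "calibration",
    "CalibrationReport",
    "net_benefit",
    "decision_curve",
    "ThresholdPoint",
    "bootstrap_optimism",
    "fairness_audit",
    "stability_intervals",
    "StabilitySummary",
    "drift_check",
    "threshold_metrics",
    "EvalReport",
    "evaluate_predictions",
]

HORIZON = 36.0


# ---------------------------------------------------------------------------
# censoring distribution and weights

def censoring_survival(times, events) -> Callable[[np.ndarray], np.ndarray]:
    """Kaplan-Meier estimate of the censoring survival function G.

    Returns a callable evaluating G left-continuously: ``G(t)`` is the
    probability of remaining uncensored strictly before ``t``.  At tied
    times events precede censorings, so a subject whose event occurs at
    the same time another is censored is weighted by the G that still
    includes the censored subject.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    order = np.argsort(t)
    t, e = t[order], e[order]
    uniq = np.unique(t)
    surv_times = [0.0]
    surv_vals = [1.0]
    g = 1.0
    n = len(t)
    for u in uniq:
        at_risk = np.sum(t >= u)
        cens = np.sum((t == u) & (~e))
        if cens and at_risk:
            g *= 1.0 - cens / at_risk
        surv_times.append(float(u))
        surv_vals.append(g)
    st = np.asarray(surv_times)
    sv = np.asarray(surv_vals)

    def G(query):
        q = np.asarray(query, dtype=float)
        # left-continuous: value just before q -> last jump strictly below q
        idx = np.searchsorted(st, q, side="left") - 1
        idx = np.clip(idx, 0, len(sv) - 1)
        out = sv[idx]
        return float(out) if np.isscalar(query) else out

    return G


def ipcw_weights(times, events, horizon: float = HORIZON):
    """Per-subject IPCW weights and 36-month labels.

    Events by the horizon get weight 1/G(T-), horizon survivors get
    1/G(horizon); subjects censored before the horizon are
    indeterminate (weight 0).  Returns (labels, weights, determinable).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    G = censoring_survival(t, e)
    case = e & (t <= horizon)
    ctrl = t > horizon
    w = np.zeros(len(t))
    g_case = G(t[case]) if case.any() else np.array([])
    if case.any():
        if np.any(g_case <= 0):
            raise DomainError("censoring survival vanished before an event time")
        w[case] = 1.0 / g_case
    if ctrl.any():
        g_tau = G(horizon + 1e-9)  # survivors: still under observation at tau
        if g_tau <= 0:
            raise DomainError("censoring survival vanished at the horizon")
        w[ctrl] = 1.0 / g_tau
    y = case.astype(float)
    return y, w, case | ctrl


# ---------------------------------------------------------------------------
# discrimination

def auroc_ipcw(preds, times, events, horizon: float = HORIZON) -> float:
    """Cumulative/dynamic time-dependent AUROC at the horizon with
    Kaplan-Meier censoring weights.

    Equals the empirical AUC exactly when no censoring occurs before
    the horizon.
    """
    p = np.asarray(preds, dtype=float)
    y, w, det = ipcw_weights(times, events, horizon)
    if y[det].sum() == 0 or (det & (y == 0)).sum() == 0:
        raise DomainError("need at least one case and one control by the horizon")
    return float(roc_auc_score(y[det], p[det], sample_weight=w[det]))


def unos_c(preds, times, events, tau: Optional[float] = None) -> float:
    """Censoring-robust concordance (inverse-censoring-survival^2 weights).

    Usable pairs: i experienced the event, strictly before j's time
    (and before ``tau`` when given); each pair is weighted by
    1/G(T_i)^2.  Without censoring this reduces to Harrell's C.
    """
    p = np.asarray(preds, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    G = censoring_survival(t, e)
    anchors = e if tau is None else (e & (t <= tau))
    if not anchors.any():
        raise DomainError("no usable anchor events")
    gi = G(t[anchors])
    if np.any(gi <= 0):
        raise DomainError("censoring survival vanished before an anchor event")
    wi = 1.0 / gi**2
    num = 0.0
    den = 0.0
    ti = t[anchors]
    pi = p[anchors]
    chunk = 2048
    for start in range(0, len(ti), chunk):
        sl = slice(start, start + chunk)
        later = t[None, :] > ti[sl, None]
        conc = (pi[sl, None] > p[None, :]) & later
        tied = (pi[sl, None] == p[None, :]) & later
        num += float((wi[sl, None] * (conc + 0.5 * tied)).sum())
        den += float((wi[sl] * later.sum(axis=1)).sum())
    if den == 0:
        raise DomainError("no comparable pairs")
    return num / den


def auprc36(preds, times, events, horizon: float = HORIZON) -> float:
    """IPCW-weighted area under the precision-recall curve at the horizon."""
    p = np.asarray(preds, dtype=float)
    y, w, det = ipcw_weights(times, events, horizon)
    if y[det].sum() == 0:
        raise DomainError("no events by the horizon")
    return float(average_precision_score(y[det], p[det], sample_weight=w[det]))


def brier36(preds, times, events, horizon: float = HORIZON) -> float:
    """Time-dependent Brier score at the horizon (IPCW-weighted)."""
    p = np.asarray(preds, dtype=float)
    y, w, det = ipcw_weights(times, events, horizon)
    return float(np.sum(w[det] * (p[det] - y[det]) ** 2) / len(p))


# ---------------------------------------------------------------------------
# calibration

@dataclass
class CalibrationReport:
    table: pd.DataFrame  # decile, n, pred_mean, observed, ci_lo, ci_hi
    slope: float
    intercept: float


def _km_event_prob(times, events, horizon: float) -> tuple[float, float, float]:
    """1 - KM survival at horizon with a Greenwood 95% CI (log-log)."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter(alpha=0.05)
    km.fit(np.asarray(times, float), np.asarray(events, bool))
    s = float(km.survival_function_at_times(horizon).iloc[0])
    ci = km.confidence_interval_
    idx = ci.index.to_numpy(dtype=float)
    pos = np.searchsorted(idx, horizon, side="right") - 1
    if pos < 0:
        return 1.0 - s, 0.0, 1.0
    lo_s, hi_s = ci.iloc[pos, 0], ci.iloc[pos, 1]
    return 1.0 - s, 1.0 - float(hi_s), 1.0 - float(lo_s)


def _cloglog(p: np.ndarray) -> np.ndarray:
    q = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(-np.log(1.0 - q))


def calibration(preds, times, events, horizon: float = HORIZON, n_bins: int = 10) -> CalibrationReport:
    """Decile calibration against Kaplan-Meier observed risk, plus a
    survival calibration slope and intercept.

    Slope: coefficient of a proportional-hazards regression of the
    outcome on the single covariate cloglog(predicted risk) (ideal 1).
    Intercept: overall KM-observed minus mean predicted on the
    complementary-log-log scale (ideal 0).
    """
    from lifelines import CoxPHFitter

    p = np.asarray(preds, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(p) < 100:
        raise DomainError("calibration deciles need n >= 100")
    bins = pd.qcut(p, n_bins, labels=False, duplicates="drop")
    rows = []
    for b in sorted(pd.unique(bins)):
        mask = bins == b
        obs, lo, hi = _km_event_prob(t[mask], e[mask], horizon)
        rows.append({
            "decile": int(b) + 1, "n": int(mask.sum()),
            "pred_mean": float(p[mask].mean()),
            "observed": obs, "ci_lo": lo, "ci_hi": hi,
        })
    table = pd.DataFrame(rows)

    df = pd.DataFrame({"z": _cloglog(p), "T": t, "E": e.astype(int)})
    cph = CoxPHFitter()
    cph.fit(df, "T", "E")
    slope = float(cph.params_["z"])
    obs_all, _, _ = _km_event_prob(t, e, horizon)
    intercept = float(_cloglog(np.array([obs_all]))[0] - _cloglog(np.array([p.mean()]))[0])
    return CalibrationReport(table=table, slope=slope, intercept=intercept)


# ---------------------------------------------------------------------------
# decision curves

@dataclass(frozen=True)
class ThresholdPoint:
    pt: float
    tp: float
    fp: float
    n: float
    nb: float
    nb_treat_all: float
    delta_nb: float
    events_prevented_per_1000: float
    sensitivity: float
    specificity: float


def net_benefit(tp: float, fp: float, n: float, pt: float) -> float:
    """NB(t) = TP/n - (FP/n) * pt / (1 - pt)."""
    if not 0.0 <= pt < 1.0:
        raise DomainError(f"risk threshold must be in [0, 1), got {pt}")
    return tp / n - (fp / n) * (pt / (1.0 - pt))


def decision_curve(
    preds, times, events,
    thresholds: Sequence[float] = tuple(np.round(np.arange(0.05, 0.2501, 0.01), 4)),
    horizon: float = HORIZON,
) -> list[ThresholdPoint]:
    """Decision-curve analysis across risk thresholds (default 5%-25%).

    Horizon outcomes for censored patients are handled by IPCW; with
    no censoring TP/FP are plain counts.  The clinical-impact summary
    per threshold is 1000 * (NB_model - NB_treat-all).
    """
    p = np.asarray(preds, dtype=float)
    y, w, det = ipcw_weights(times, events, horizon)
    y, w, p = y[det], w[det], p[det]
    n = float(w.sum())
    pos_mass = float((w * y).sum())
    prev = pos_mass / n
    out = []
    for pt in thresholds:
        flagged = p >= pt
        tp = float((w * y)[flagged].sum())
        fp = float((w * (1 - y))[flagged].sum())
        nb = net_benefit(tp, fp, n, pt)
        nb_all = prev - (1.0 - prev) * pt / (1.0 - pt)
        sens = tp / pos_mass if pos_mass else np.nan
        neg_mass = n - pos_mass
        spec = 1.0 - fp / neg_mass if neg_mass else np.nan
        out.append(ThresholdPoint(
            pt=float(pt), tp=tp, fp=fp, n=n, nb=nb, nb_treat_all=nb_all,
            delta_nb=nb - nb_all, events_prevented_per_1000=1000.0 * (nb - nb_all),
            sensitivity=sens, specificity=spec,
        ))
    return out


# ---------------------------------------------------------------------------
# optimism and stability

def _harrell_c(preds, times, events) -> float:
    from lifelines.utils import concordance_index

    return float(concordance_index(times, -np.asarray(preds, float), events))


def bootstrap_optimism(
    fit_fn: Callable[[pd.DataFrame], Callable[[pd.DataFrame], np.ndarray]],
    cohort: Cohort,
    B: int = 1000,
    seed: int = 42,
    method: str = "bca",
) -> dict:
    """Bootstrap optimism of the concordance statistic with patient-level
    resampling.

    ``fit_fn(train_frame)`` must return a prediction closure.  Optimism
    is the mean over replicates of (apparent C on the bootstrap sample
    minus C of the bootstrap model on the original data).  The BCa
    interval for C uses the replicate distribution, with acceleration
    from a leave-one-out jackknife of the original model's C.
    """
    if B < 2:
        raise ConfigError("bootstrap optimism needs B >= 2 replicates")
    rng = np.random.default_rng(seed)
    df = cohort.df
    predict = fit_fn(df)
    c_apparent = _harrell_c(predict(df), df["followup_months"], df["event"])
    opts, c_boot = [], []
    failed = 0
    for _ in range(B):
        idx = rng.integers(0, len(df), len(df))
        boot = df.iloc[idx].reset_index(drop=True)
        try:
            pred_b = fit_fn(boot)
            c_app_b = _harrell_c(pred_b(boot), boot["followup_months"], boot["event"])
            c_orig_b = _harrell_c(pred_b(df), df["followup_months"], df["event"])
        except Exception:  # a replicate that fails to refit is dropped, counted
            failed += 1
            continue
        opts.append(c_app_b - c_orig_b)
        c_boot.append(c_app_b)
    if not opts:
        raise ConfigError("all bootstrap replicates failed to refit")
    optimism = float(np.mean(opts))
    c_boot = np.asarray(c_boot)
    interval = _bca_interval(c_boot, c_apparent, predict, df) if method == "bca" else (
        float(np.percentile(c_boot, 2.5)), float(np.percentile(c_boot, 97.5)))
    return {
        "c_apparent": c_apparent,
        "optimism": optimism,
        "c_corrected": c_apparent - optimism,
        "ci": interval,
        "replicates_failed": failed,
    }


def _bca_interval(boot_stats, stat, predict, df, alpha=0.05):
    prop = float(np.mean(boot_stats < stat))
    z0 = norm.ppf(np.clip(prop, 1e-6, 1 - 1e-6))
    # acceleration from jackknife of the evaluation (fixed model)
    n = len(df)
    take = min(n, 200)  # subsampled jackknife keeps this O(take * C-cost)
    jack = []
    for i in np.linspace(0, n - 1, take).astype(int):
        sub = df.drop(index=df.index[i])
        jack.append(_harrell_c(predict(sub), sub["followup_months"], sub["event"]))
    jack = np.asarray(jack)
    diffs = jack.mean() - jack
    denom = 6.0 * (np.sum(diffs**2) ** 1.5)
    a = float(np.sum(diffs**3) / denom) if denom > 0 else 0.0
    lo_q = norm.cdf(z0 + (z0 + norm.ppf(alpha / 2)) / (1 - a * (z0 + norm.ppf(alpha / 2))))
    hi_q = norm.cdf(z0 + (z0 + norm.ppf(1 - alpha / 2)) / (1 - a * (z0 + norm.ppf(1 - alpha / 2))))
    return (float(np.percentile(boot_stats, 100 * lo_q)),
            float(np.percentile(boot_stats, 100 * hi_q)))


@dataclass
class StabilitySummary:
    widths_pp: np.ndarray          # per-patient 95% PI width, percentage points
    median_width: float
    mad: float
    cv: float
    band_fractions: dict[str, float]           # <5 / 5-10 / >10 pp
    bands_by_category: pd.DataFrame


def stability_intervals(
    fit_fn: Callable[[pd.DataFrame], Callable[[pd.DataFrame], np.ndarray]],
    train: Cohort,
    patients: pd.DataFrame,
    B: int = 1000,
    seed: int = 42,
    category_cuts: tuple[float, float, float] = (0.05, 0.15, 0.30),
) -> StabilitySummary:
    """Individual-prediction stability via bootstrap refits.

    Refits the model on B patient-level resamples of the training
    cohort, predicts each patient under every refit, and summarises
    the 95% interval width of each patient's predicted risk.
    """
    rng = np.random.default_rng(seed)
    df = train.df
    preds = np.empty((B, len(patients)))
    for b in range(B):
        idx = rng.integers(0, len(df), len(df))
        predict = fit_fn(df.iloc[idx].reset_index(drop=True))
        preds[b] = np.asarray(predict(patients), dtype=float)
    lo, hi = np.percentile(preds, [2.5, 97.5], axis=0)
    widths = 100.0 * (hi - lo)
    mean_pred = preds.mean(axis=0)
    med = float(np.median(widths))
    mad = float(np.median(np.abs(widths - med)))
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = float(np.nanmedian(np.where(mean_pred > 0, preds.std(axis=0) / mean_pred, np.nan)))
    bands = np.select([widths < 5.0, widths <= 10.0], ["<5", "5-10"], default=">10")
    band_fr = {b: float(np.mean(bands == b)) for b in ("<5", "5-10", ">10")}
    cats = np.select(
        [mean_pred < category_cuts[0], mean_pred < category_cuts[1], mean_pred < category_cuts[2]],
        ["low", "moderate", "high"], default="very_high",
    )
    by_cat = (
        pd.DataFrame({"category": cats, "band": bands})
        .groupby("category")["band"].value_counts(normalize=True).rename("fraction").reset_index()
    )
    return StabilitySummary(widths, med, mad, cv, band_fr, by_cat)


# ---------------------------------------------------------------------------
# fairness and drift

def _binary_slope(preds, y) -> float:
    """Logistic calibration slope of binary outcomes on logit(p) (ideal 1)."""
    from scipy.special import logit as _logit
    from sklearn.linear_model import LogisticRegression

    z = _logit(np.clip(np.asarray(preds, float), 1e-9, 1 - 1e-9)).reshape(-1, 1)
    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    lr.fit(z, np.asarray(y, int))
    return float(lr.coef_[0, 0])


def fairness_audit(
    preds,
    outcomes,
    subgroups: dict[str, pd.Series],
    delta_threshold: float = 0.03,
    slope_range: tuple[float, float] = (0.8, 1.2),
) -> pd.DataFrame:
    """Subgroup discrimination/calibration audit with violation flags.

    For each grouping the largest subgroup is the reference; a
    violation is |delta-AUROC| > 0.03 versus the reference or a
    calibration slope outside [0.8, 1.2].  Subgroups lacking both
    outcome classes are flagged unassessable rather than scored.
    """
    p = np.asarray(preds, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    rows = []
    for gname, labels in subgroups.items():
        labels = pd.Series(np.asarray(labels, dtype=object))
        counts = labels.value_counts()
        ref_level = counts.index[0]
        ref_mask = (labels == ref_level).to_numpy()
        ref_auc = roc_auc_score(y[ref_mask], p[ref_mask]) if len(np.unique(y[ref_mask])) == 2 else np.nan
        for level in counts.index:
            mask = (labels == level).to_numpy()
            if len(np.unique(y[mask])) < 2:
                rows.append({"grouping": gname, "subgroup": str(level), "n": int(mask.sum()),
                             "auroc": np.nan, "delta_auroc": np.nan, "slope": np.nan,
                             "violation": False, "unassessable": True})
                continue
            auc = roc_auc_score(y[mask], p[mask])
            slope = _binary_slope(p[mask], y[mask])
            delta = auc - ref_auc if np.isfinite(ref_auc) else np.nan
            violation = (np.isfinite(delta) and abs(delta) > delta_threshold) or not (
                slope_range[0] <= slope <= slope_range[1]
            )
            rows.append({"grouping": gname, "subgroup": str(level), "n": int(mask.sum()),
                         "auroc": float(auc), "delta_auroc": float(delta) if np.isfinite(delta) else np.nan,
                         "slope": slope, "violation": bool(violation), "unassessable": False})
    return pd.DataFrame(rows)


def drift_check(
    current: dict,
    baseline: dict,
    auroc_drop: float = 0.05,
    slope_range: tuple[float, float] = (0.85, 1.15),
) -> list[str]:
    """Deployment drift triggers: retrain when validation AUROC drops by
    more than 0.05 or the calibration slope leaves [0.85, 1.15]."""
    flags = []
    if baseline.get("auroc36") is not None and current.get("auroc36") is not None:
        if baseline["auroc36"] - current["auroc36"] > auroc_drop:
            flags.append(
                f"auroc_drop: {baseline['auroc36']:.3f} -> {current['auroc36']:.3f} "
                f"(drop > {auroc_drop})"
            )
    slope = current.get("calibration_slope")
    if slope is not None and not (slope_range[0] <= slope <= slope_range[1]):
        flags.append(f"calibration_slope {slope:.3f} outside {slope_range}")
    return flags


def threshold_metrics(preds, outcomes, pts: Sequence[float]) -> pd.DataFrame:
    """Sensitivity / false-positive-rate across thresholds with monotone
    cubic-spline interpolation between exactly-computed anchor points."""
    p = np.asarray(preds, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    anchors = np.unique(np.concatenate([[0.0, 1.0], np.round(np.linspace(0, 1, 51), 6)]))
    sens_a = np.array([(p[y == 1] >= t).mean() if (y == 1).any() else np.nan for t in anchors])
    fpr_a = np.array([(p[y == 0] >= t).mean() if (y == 0).any() else np.nan for t in anchors])
    sens_i = PchipInterpolator(anchors, sens_a)
    fpr_i = PchipInterpolator(anchors, fpr_a)
    q = np.asarray(pts, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise DomainError("thresholds must lie in [0, 1]")
    return pd.DataFrame({"pt": q, "sensitivity": sens_i(q), "fpr": fpr_i(q)})


# ---------------------------------------------------------------------------
# report assembly

@dataclass
class EvalReport:
    auroc36: float
    unos_c: float
    auprc36: float
    brier36: float
    calibration_slope: float
    calibration_intercept: float
    calibration_table: pd.DataFrame
    dca: list[ThresholdPoint]
    fairness: Optional[pd.DataFrame] = None
    stability: Optional[StabilitySummary] = None
    drift_flags: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "auroc36": self.auroc36,
            "unos_c": self.unos_c,
            "auprc36": self.auprc36,
            "brier36": self.brier36,
            "calibration_slope": self.calibration_slope,
            "calibration_intercept": self.calibration_intercept,
            "n_drift_flags": len(self.drift_flags),
        }


def evaluate_predictions(
    preds, times, events,
    horizon: float = HORIZON,
    thresholds: Sequence[float] = tuple(np.round(np.arange(0.05, 0.2501, 0.05), 4)),
) -> EvalReport:
    """Core discrimination + calibration + decision-curve report for one
    prediction set."""
    calib = calibration(preds, times, events, horizon)
    return EvalReport(
        auroc36=auroc_ipcw(preds, times, events, horizon),
        unos_c=unos_c(preds, times, events, tau=horizon),
        auprc36=auprc36(preds, times, events, horizon),
        brier36=brier36(preds, times, events, horizon),
        calibration_slope=calib.slope,
        calibration_intercept=calib.intercept,
        calibration_table=calib.table,
        dca=decision_curve(preds, times, events, thresholds, horizon),
    )
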