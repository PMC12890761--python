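"""Evaluation suite: IPCW discrimination against brute-force oracles,
calibration, decision curves, optimism, fairness, stability, drift."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from dkdrisk._errors import ConfigError, DomainError
from dkdrisk.core_types import Cohort
from dkdrisk.evaluate import (
    auprc36,
    auroc_ipcw,
    bootstrap_optimism,
    brier36,
    calibration,
    censoring_survival,
    decision_curve,
    drift_check,
    evaluate_predictions,
    fairness_audit,
    net_benefit,
    stability_intervals,
    threshold_metrics,
    unos_c,
)


def brute_force_auroc(preds, times, events, horizon=36.0):
    """Exhaustive weighted-pair oracle sharing only the censoring KM."""
    G = censoring_survival(times, events)
    p = np.asarray(preds, float)
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    case = e & (t <= horizon)
    ctrl = t > horizon
    num = den = 0.0
    for i in np.flatnonzero(case):
        wi = 1.0 / G(t[i])
        for j in np.flatnonzero(ctrl):
            wj = 1.0 / G(horizon + 1e-9)
            num += wi * wj * ((p[i] > p[j]) + 0.5 * (p[i] == p[j]))
            den += wi * wj
    return num / den


def brute_force_unos(preds, times, events, tau=None):
    G = censoring_survival(times, events)
    p = np.asarray(preds, float)
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    num = den = 0.0
    for i in range(len(t)):
        if not e[i] or (tau is not None and t[i] > tau):
            continue
        wi = 1.0 / G(t[i]) ** 2
        for j in range(len(t)):
            if t[j] > t[i]:
                num += wi * ((p[i] > p[j]) + 0.5 * (p[i] == p[j]))
                den += wi
    return num / den


CENSORED_FIXTURE = dict(
    preds=np.array([0.9, 0.2, 0.7, 0.4, 0.6, 0.1, 0.5, 0.3]),
    times=np.array([5.0, 40.0, 12.0, 20.0, 40.0, 40.0, 30.0, 38.0]),
    events=np.array([1, 0, 1, 0, 0, 0, 1, 0], bool),
)


class TestDiscriminationOracles:
    def test_ipcw_auroc_matches_pair_enumeration(self):
        f = CENSORED_FIXTURE
        assert auroc_ipcw(**f) == pytest.approx(brute_force_auroc(**f), abs=1e-10)

    def test_unos_c_matches_pair_enumeration(self):
        f = CENSORED_FIXTURE
        assert unos_c(f["preds"], f["times"], f["events"]) == pytest.approx(
            brute_force_unos(f["preds"], f["times"], f["events"]), abs=1e-10
        )

    def test_uncensored_auroc_reduces_to_empirical(self):
        rng = np.random.default_rng(0)
        p = rng.random(400)
        t = np.where(rng.random(400) < 0.3, rng.uniform(1, 36, 400), 40.0)
        e = t <= 36
        assert auroc_ipcw(p, t, e) == pytest.approx(roc_auc_score(e, p), abs=1e-12)

    def test_uncensored_unos_reduces_to_harrell(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(1)
        p = rng.random(300)
        t = rng.uniform(1, 60, 300)
        e = np.ones(300, bool)
        assert unos_c(p, t, e) == pytest.approx(
            concordance_index(t, -p, e), abs=1e-10
        )

    def test_perfect_separation_is_one(self):
        p = np.array([0.9, 0.8, 0.1, 0.2])
        t = np.array([10.0, 20.0, 40.0, 50.0])
        e = np.array([1, 1, 0, 0], bool)
        assert auroc_ipcw(p, t, e) == 1.0

    def test_null_predictor_near_half(self):
        rng = np.random.default_rng(2)
        n = 4000
        p = rng.random(n)
        t = np.where(rng.random(n) < 0.2, rng.uniform(1, 36, n), 48.0)
        e = t <= 36
        assert auroc_ipcw(p, t, e) == pytest.approx(0.5, abs=0.03)

    def test_anticoncordant_complements(self):
        f = CENSORED_FIXTURE
        c = unos_c(f["preds"], f["times"], f["events"])
        c_anti = unos_c(-f["preds"], f["times"], f["events"])
        assert c + c_anti == pytest.approx(1.0, abs=1e-10)

    def test_agrees_with_independent_survival_library(self):
        """Cross-check both IPCW metrics against scikit-survival."""
        from sksurv.metrics import concordance_index_ipcw, cumulative_dynamic_auc
        from sksurv.util import Surv

        rng = np.random.default_rng(0)
        n = 300
        p = rng.random(n)
        t = np.round(rng.uniform(1, 60, n), 3)
        e = rng.random(n) < 0.6
        y = Surv.from_arrays(e, t)
        ref_auc, _ = cumulative_dynamic_auc(y, y, p, [36.0])
        assert auroc_ipcw(p, t, e, 36.0) == pytest.approx(ref_auc[0], abs=1e-12)
        ref_c = concordance_index_ipcw(y, y, p, tau=36.0)[0]
        assert unos_c(p, t, e, tau=36.0) == pytest.approx(ref_c, abs=1e-12)

    def test_no_events_is_error(self):
        with pytest.raises(DomainError):
            auroc_ipcw([0.1, 0.2], [40.0, 50.0], [False, False])

    def test_bounds(self):
        f = CENSORED_FIXTURE
        assert 0.0 <= auroc_ipcw(**f) <= 1.0
        assert 0.0 <= unos_c(f["preds"], f["times"], f["events"]) <= 1.0


class TestBrierAndAuprc:
    def test_perfect_predictions_zero_brier(self):
        t = np.array([10.0, 40.0, 12.0, 50.0])
        e = np.array([1, 0, 1, 0], bool)
        p = np.array([1.0, 0.0, 1.0, 0.0])
        assert brier36(p, t, e) == pytest.approx(0.0, abs=1e-12)

    def test_constant_prediction_closed_form(self):
        # uncensored: Brier = mean((p - y)^2) = q(1-p)^2 + (1-q)p^2
        t = np.array([10.0] * 3 + [40.0] * 7)
        e = t <= 36
        p = np.full(10, 0.3)
        expected = 0.3 * 0.7**2 + 0.7 * 0.3**2
        assert brier36(p, t, e) == pytest.approx(expected, abs=1e-12)

    def test_all_positive_auprc_is_one(self):
        t = np.array([5.0, 10.0, 20.0])
        e = np.ones(3, bool)
        assert auprc36(np.array([0.5, 0.6, 0.7]), t, e) == pytest.approx(1.0)


class TestCalibration:
    def test_uncensored_deciles_equal_raw_fractions(self):
        rng = np.random.default_rng(3)
        n = 1000
        p = rng.uniform(0.05, 0.9, n)
        y = rng.random(n) < p
        t = np.where(y, 10.0, 40.0)
        rep = calibration(p, t, y, 36.0)
        bins = pd.qcut(p, 10, labels=False)
        for _, row in rep.table.iterrows():
            mask = bins == row["decile"] - 1
            assert row["observed"] == pytest.approx(y[mask].mean(), abs=1e-9)

    def test_true_risk_scoring_recovers_unit_slope(self, small_cohort):
        df = small_cohort.df
        rep = calibration(df["true_risk36"], df["followup_months"], df["event"])
        assert rep.slope == pytest.approx(1.0, abs=0.12)
        assert abs(rep.intercept) < 0.15

    def test_overdispersed_predictions_detected(self, small_cohort):
        df = small_cohort.df
        rep = calibration(df["true_risk36"] ** 2, df["followup_months"], df["event"])
        assert abs(rep.slope - 1.0) > 0.15 or abs(rep.intercept) > 0.3

    def test_needs_hundred_patients(self):
        with pytest.raises(DomainError):
            calibration(np.full(50, 0.2), np.full(50, 40.0), np.zeros(50, bool))

    def test_decile_table_covers_everyone(self, small_cohort):
        df = small_cohort.df
        rep = calibration(df["true_risk36"], df["followup_months"], df["event"])
        assert rep.table["n"].sum() == len(df)

    def test_greenwood_intervals_cover_true_risks(self, small_cohort):
        df = small_cohort.df
        rep = calibration(df["true_risk36"], df["followup_months"], df["event"])
        covered = (
            (rep.table["pred_mean"] >= rep.table["ci_lo"])
            & (rep.table["pred_mean"] <= rep.table["ci_hi"])
        ).mean()
        assert covered >= 0.8


class TestDecisionCurve:
    def test_worked_formula(self):
        assert net_benefit(87, 190, 1000, 0.1) == pytest.approx(0.06589, abs=1e-5)

    def test_threshold_domain(self):
        with pytest.raises(DomainError):
            net_benefit(10, 10, 100, 1.0)

    def test_low_threshold_limit_is_tp_rate(self):
        t = np.array([10.0] * 20 + [40.0] * 80)
        e = t <= 36
        p = np.linspace(0.01, 0.99, 100)
        pts = decision_curve(p, t, e, thresholds=[1e-9])
        assert pts[0].nb == pytest.approx(pts[0].tp / pts[0].n, abs=1e-6)

    def test_treat_none_is_zero_everywhere(self):
        # a model that flags nobody has zero net benefit at any threshold
        t = np.array([10.0] * 20 + [40.0] * 80)
        e = t <= 36
        pts = decision_curve(np.zeros(100), t, e, thresholds=[0.05, 0.15, 0.25])
        assert all(pt.nb == 0.0 for pt in pts)

    def test_net_benefit_never_exceeds_prevalence(self, small_cohort):
        df = small_cohort.df
        pts = decision_curve(
            df["true_risk36"], df["followup_months"], df["event"],
            thresholds=np.arange(0.05, 0.26, 0.05),
        )
        prev = pts[0].tp / pts[0].n + 1e-12
        assert all(pt.nb <= prev + 1e-9 for pt in pts)

    def test_events_prevented_is_thousandfold_delta(self, small_cohort):
        df = small_cohort.df
        pts = decision_curve(df["true_risk36"], df["followup_months"], df["event"],
                             thresholds=[0.10])
        assert pts[0].events_prevented_per_1000 == pytest.approx(1000 * pts[0].delta_nb)


class TestBootstrapOptimism:
    def _cohort(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "x": rng.normal(size=n),
        })
        risk = 1 / (1 + np.exp(-df["x"]))
        df["followup_months"] = np.where(rng.random(n) < risk, 12.0, 48.0)
        df["event"] = df["followup_months"] <= 36
        return Cohort(df)

    def test_fixed_predictor_near_zero_optimism(self):
        cohort = self._cohort()

        def fit_fn(train):
            return lambda d: d["x"].to_numpy()

        out = bootstrap_optimism(fit_fn, cohort, B=40, seed=1)
        assert abs(out["optimism"]) < 0.01
        assert out["ci"][0] <= out["c_apparent"] <= out["ci"][1]

    def test_memorising_learner_shows_optimism(self):
        cohort = self._cohort()

        def fit_fn(train):
            lookup = dict(zip(train["patient_id"], train["event"].astype(float)))
            return lambda d: np.array([lookup.get(pid, 0.5) for pid in d["patient_id"]])

        out = bootstrap_optimism(fit_fn, cohort, B=40, seed=2)
        assert out["optimism"] > 0.05

    def test_single_replicate_rejected(self):
        with pytest.raises(ConfigError):
            bootstrap_optimism(lambda d: (lambda x: np.zeros(len(x))), self._cohort(), B=1)


class TestFairness:
    def _population(self, seed=0, n=6000):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.02, 0.6, n)
        y = (rng.random(n) < p).astype(int)
        group = np.where(rng.random(n) < 0.5, "g1", "g2")
        return p, y, group

    def test_identical_quality_no_flags(self):
        p, y, group = self._population()
        table = fairness_audit(p, y, {"group": pd.Series(group)})
        assert not table["violation"].any()

    def test_degraded_subgroup_flagged_by_delta(self):
        p, y, group = self._population(seed=1)
        rng = np.random.default_rng(2)
        noisy = p.copy()
        mask = group == "g2"
        noisy[mask] = rng.permutation(noisy[mask])  # destroys discrimination in g2
        table = fairness_audit(noisy, y, {"group": pd.Series(group)},
                               slope_range=(-np.inf, np.inf))
        g2 = table[table["subgroup"] == "g2"].iloc[0]
        assert abs(g2["delta_auroc"]) > 0.03 and g2["violation"]

    def test_miscalibrated_subgroup_flagged_by_slope(self):
        rng = np.random.default_rng(3)
        n = 6000
        p = rng.uniform(0.05, 0.6, n)
        group = np.where(rng.random(n) < 0.5, "ref", "flat")
        # in the "flat" group outcomes depend only weakly on p -> slope < 0.8
        pp = np.where(group == "ref", p, 0.25 + 0.3 * (p - p.mean()))
        y = (rng.random(n) < pp).astype(int)
        table = fairness_audit(p, y, {"group": pd.Series(group)}, delta_threshold=np.inf)
        flat = table[table["subgroup"] == "flat"].iloc[0]
        assert flat["slope"] < 0.8 and flat["violation"]

    def test_single_class_subgroup_unassessable(self):
        p = np.array([0.2, 0.4, 0.6, 0.8])
        y = np.array([0, 0, 1, 1])
        group = pd.Series(["a", "a", "b", "b"])
        table = fairness_audit(p, y, {"g": group})
        assert table["unassessable"].all()

    def test_default_generator_predictions_unflagged(self, small_cohort):
        """No group-by-risk interaction in the generator: scoring with the
        true risks produces no fairness violations."""
        df = small_cohort.df
        det = df[~((df["censor_reason"] == "administrative")
                   & (df["followup_months"] < 36) & (~df["event"]))]
        y = ((det["event"]) & (det["followup_months"] <= 36)).astype(int)
        groups = {
            "sex": det["sex"],
            "age_band": pd.Series(np.where(det["age"] >= 65, ">=65", "<65")),
        }
        table = fairness_audit(det["true_risk36"], y, groups)
        assert not table["violation"].any()


class TestDrift:
    def test_auroc_drop_triggers(self):
        flags = drift_check({"auroc36": 0.790, "calibration_slope": 1.0},
                            {"auroc36": 0.852})
        assert any("auroc_drop" in f for f in flags)

    def test_slope_out_of_band_triggers(self):
        flags = drift_check({"auroc36": 0.85, "calibration_slope": 1.16},
                            {"auroc36": 0.85})
        assert any("calibration_slope" in f for f in flags)

    def test_unchanged_report_clean(self):
        cur = {"auroc36": 0.852, "calibration_slope": 0.98}
        assert drift_check(cur, {"auroc36": 0.852}) == []

    def test_thresholds_fire_exactly_at_cutpoints(self):
        # drop of exactly 0.05 is tolerated; beyond it triggers
        assert drift_check({"auroc36": 0.802, "calibration_slope": 1.0},
                           {"auroc36": 0.852}) == []
        assert drift_check({"auroc36": 0.8019, "calibration_slope": 1.0},
                           {"auroc36": 0.852}) != []
        assert drift_check({"auroc36": 0.85, "calibration_slope": 1.15},
                           {"auroc36": 0.85}) == []
        assert drift_check({"auroc36": 0.85, "calibration_slope": 0.849},
                           {"auroc36": 0.85}) != []


class TestThresholdMetrics:
    def test_endpoints(self):
        rng = np.random.default_rng(4)
        p = rng.random(500)
        y = (rng.random(500) < p).astype(int)
        tm = threshold_metrics(p, y, [0.0, 1.0])
        assert tm.iloc[0]["sensitivity"] == pytest.approx(1.0)
        assert tm.iloc[0]["fpr"] == pytest.approx(1.0)
        assert tm.iloc[1]["sensitivity"] == pytest.approx(0.0, abs=1e-9)
        assert tm.iloc[1]["fpr"] == pytest.approx(0.0, abs=1e-9)

    def test_interpolant_passes_through_anchors(self):
        rng = np.random.default_rng(5)
        p = rng.random(500)
        y = (rng.random(500) < p).astype(int)
        anchor = 0.5  # on the exact anchor grid
        tm = threshold_metrics(p, y, [anchor])
        assert tm.iloc[0]["sensitivity"] == pytest.approx((p[y == 1] >= anchor).mean(), abs=1e-12)


class TestStability:
    def test_deterministic_model_zero_width(self, small_cohort):
        def fit_fn(train):
            return lambda d: np.full(len(d), 0.1)

        out = stability_intervals(fit_fn, small_cohort, small_cohort.df.head(50), B=10, seed=0)
        assert np.all(out.widths_pp == 0.0)
        assert out.band_fractions["<5"] == 1.0

    def test_known_noise_scale_recovered(self, small_cohort):
        rng_holder = {"i": 0}

        def fit_fn(train):
            rng = np.random.default_rng(rng_holder["i"])
            rng_holder["i"] += 1
            offset = rng.normal(0, 0.01)
            return lambda d: np.clip(0.2 + offset + np.zeros(len(d)), 0, 1)

        out = stability_intervals(fit_fn, small_cohort, small_cohort.df.head(30), B=200, seed=1)
        # 95% interval of N(0.2, 0.01) is ~3.92 pp wide
        assert out.median_width == pytest.approx(3.92, abs=0.8)

    def test_band_fractions_sum_to_one(self, small_cohort):
        def fit_fn(train):
            return lambda d: np.full(len(d), 0.2)

        out = stability_intervals(fit_fn, small_cohort, small_cohort.df.head(20), B=5, seed=2)
        assert sum(out.band_fractions.values()) == pytest.approx(1.0)


def test_full_report_assembly(small_cohort):
    df = small_cohort.df
    report = evaluate_predictions(df["true_risk36"], df["followup_months"], df["event"])
    s = report.summary()
    assert 0.5 < s["auroc36"] <= 1.0
    assert 0.5 < s["unos_c"] <= 1.0
    assert 0.0 < s["brier36"] < 0.25
    assert abs(s["calibration_slope"] - 1.0) < 0.15
    assert len(report.dca) == 5
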