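"""Literature-coefficient risk engine: linear predictor, 36-month risk,
categories, uncertainty and clinical-gain attribution."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dkdrisk._errors import BoundsError, DomainError
from dkdrisk.core_types import PatientRecord
from dkdrisk.risk_engine import (
    Effect,
    RiskModelSpec,
    categorize,
    clinical_gain,
    contributions_frame,
    default_model_spec,
    linear_predictor,
    permutation_attribution,
    predict_frame,
    predict_risk36,
    spec_from_json,
    spec_to_json,
)

LIT_ZERO = {"family_history_ckd": 0, "nsaid_chronic": 0, "dr_severity": 0,
            "imd_quintile": 0, "sglt2i": 0, "ace_arb": 0, "glp1_ra": 0,
            "finerenone": 0, "statin": 0}


def reference_record(**overrides):
    """Patient at every effect's reference value (stage: no CKD)."""
    kw = dict(
        patient_id="ref", age=60.0, sex="female", egfr=95.0, acr=10.0,
        hba1c=7.0, diabetes_duration=0.0, bmi=25.0, sbp=120.0, smoking="never",
        medication_compliance=10.0, waist_circumference=100.0,
        lit_vars=dict(LIT_ZERO),
    )
    kw.update(overrides)
    return PatientRecord(**kw)


@pytest.fixture(scope="module")
def spec():
    return default_model_spec()


class TestLinearPredictor:
    def test_reference_patient_zero(self, spec):
        lp, contribs = linear_predictor(reference_record(), spec)
        assert lp == pytest.approx(0.0, abs=1e-12)
        assert all(abs(v) < 1e-12 for v in contribs.values())

    @pytest.mark.parametrize(
        "overrides, expected",
        [
            ({"smoking": "current"}, math.log(1.35)),
            ({"age": 70.0}, math.log(1.16)),
            ({"sex": "male"}, math.log(1.19)),
            ({"hba1c": 8.0}, math.log(1.13)),
            ({"medication_compliance": 8.0}, math.log(1.30)),
        ],
    )
    def test_single_deviation_contributions(self, spec, overrides, expected):
        lp, _ = linear_predictor(reference_record(**overrides), spec)
        assert lp == pytest.approx(expected, abs=1e-10)

    def test_lit_var_effects(self, spec):
        rec = reference_record()
        rec.lit_vars["sglt2i"] = 1
        lp, contribs = linear_predictor(rec, spec)
        assert lp == pytest.approx(math.log(0.61), abs=1e-10)
        assert contribs["sglt2i"] == pytest.approx(math.log(0.61), abs=1e-10)

    def test_retinopathy_grades(self, spec):
        for grade, hr in [(1, 2.9), (2, 5.8), (3, 10.2), (4, 16.6)]:
            rec = reference_record()
            rec.lit_vars["dr_severity"] = grade
            lp, _ = linear_predictor(rec, spec)
            assert lp == pytest.approx(math.log(hr), abs=1e-10)

    def test_missing_features_contribute_zero(self, spec):
        rec = PatientRecord(patient_id="sparse", egfr=95.0, age=60.0)
        lp, _ = linear_predictor(rec, spec)
        assert lp == pytest.approx(0.0, abs=1e-12)

    def test_contributions_sum_to_lp(self, spec):
        rec = reference_record(age=73.0, hba1c=9.2, bmi=33.0, sbp=150.0, smoking="current")
        rec.lit_vars.update({"dr_severity": 2, "sglt2i": 1})
        lp, contribs = linear_predictor(rec, spec)
        assert sum(contribs.values()) == pytest.approx(lp, abs=1e-12)

    def test_out_of_bounds_refused(self, spec):
        with pytest.raises(BoundsError, match="egfr"):
            linear_predictor(reference_record(egfr=160.0), spec)


class TestPredictRisk36:
    def test_reference_no_ckd_risk(self, spec):
        out = predict_risk36(reference_record(), spec)
        assert out.risk36 == pytest.approx(1 - math.exp(-36 * 0.00048), abs=1e-8)
        assert out.category == "low"

    def test_lone_smoker_risk(self, spec):
        out = predict_risk36(reference_record(smoking="current"), spec)
        assert out.risk36 == pytest.approx(1 - math.exp(-36 * 0.00048 * 1.35), abs=1e-8)

    def test_stage_base_hazard_selected(self, spec):
        out = predict_risk36(reference_record(egfr=22.0), spec)  # stage 4 midpoint
        assert out.risk36 == pytest.approx(1 - math.exp(-36 * 0.016), abs=1e-8)

    def test_uncertainty_counts_supplied_features(self, spec):
        full = predict_risk36(reference_record(), spec)
        # 11 observed + 9 literature variables supplied
        assert full.uncertainty == pytest.approx(0.05 + 20 * 0.01, abs=1e-12)
        sparse = predict_risk36(PatientRecord(patient_id="s", egfr=95.0, age=60.0), spec)
        assert sparse.uncertainty == pytest.approx(0.05 + 2 * 0.01, abs=1e-12)
        assert sparse.interval[0] <= sparse.risk36 <= sparse.interval[1]

    def test_monotone_in_risk_factors_and_protective(self, spec):
        base = predict_risk36(reference_record(), spec).risk36
        worse = predict_risk36(reference_record(hba1c=10.0), spec).risk36
        assert worse > base
        rec = reference_record()
        rec.lit_vars["sglt2i"] = 1
        protected = predict_risk36(rec, spec).risk36
        assert protected < base

    def test_risk_below_one_even_extreme(self, spec):
        rec = reference_record(egfr=16.0, acr=4000.0, hba1c=15.0, sbp=210.0,
                               bmi=55.0, age=95.0, smoking="current",
                               medication_compliance=0.0, diabetes_duration=50.0)
        rec.lit_vars.update({"dr_severity": 4, "family_history_ckd": 1, "nsaid_chronic": 1})
        out = predict_risk36(rec, spec)
        assert 0.99 < out.risk36 < 1.0

    def test_frame_prediction_matches_record_path(self, spec, small_cohort):
        df = small_cohort.df.head(50)
        frame_out = predict_frame(df, spec)
        cohort_head = type(small_cohort)(df, small_cohort.provenance)
        for i, rec in enumerate(cohort_head.records()):
            if rec.egfr is None:
                continue
            rec_out = predict_risk36(rec, spec)
            assert frame_out["risk36"].iloc[i] == pytest.approx(rec_out.risk36, abs=1e-9)


class TestCategorize:
    @pytest.mark.parametrize(
        "risk, category",
        [(0.0, "low"), (0.04, "low"), (0.05, "moderate"), (0.10, "moderate"),
         (0.149999, "moderate"), (0.15, "high"), (0.30, "very_high"),
         (0.35, "very_high"), (1.0, "very_high")],
    )
    def test_left_closed_bins(self, risk, category):
        assert categorize(risk) == category

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            categorize(1.2)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_total_on_unit_interval(self, risk):
        assert categorize(risk) in {"low", "moderate", "high", "very_high"}


class TestClinicalGain:
    def test_single_effect_gets_everything(self):
        spec = RiskModelSpec(effects=(
            Effect("hba1c", "hba1c", "per_unit", 7.0, (math.log(1.13),), (0.0,)),
        ))
        df = pd.DataFrame({"hba1c": [6.0, 8.0, 9.0], "egfr": [95.0] * 3})
        gains = clinical_gain(df, spec)
        assert gains["hba1c"] == pytest.approx(100.0)

    def test_symmetric_effects_split_evenly(self):
        b = math.log(1.2)
        spec = RiskModelSpec(effects=(
            Effect("a", "a", "per_unit", 0.0, (b,), (0.0,)),
            Effect("b", "b", "per_unit", 0.0, (b,), (0.0,)),
        ))
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(0, 1, 4000), "b": rng.normal(0, 1, 4000)})
        gains = clinical_gain(df, spec)
        assert gains["a"] == pytest.approx(50.0, abs=2.0)

    def test_kidney_markers_dominate_on_synthetic_cohort(self, spec, small_cohort):
        df = small_cohort.df.copy()
        for name in LIT_ZERO:
            df[f"lit_{name}"] = df[f"true_{name}"]
        gains = clinical_gain(df, spec)
        kidney = gains["egfr"] + gains["acr"]
        others = {k: v for k, v in gains.items() if k not in ("egfr", "acr")}
        assert kidney > max(others.values())

    def test_constant_predictor_warns_all_zero(self):
        spec = RiskModelSpec(effects=(
            Effect("a", "a", "per_unit", 0.0, (0.0,), (0.0,)),
        ))
        df = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            gains = clinical_gain(df, spec)
        assert gains["a"] == 0.0

    def test_iqr_gradient_reproduces_printed_hr(self, spec, small_cohort):
        """Exponentiating the attribution gradient over the IQR of a
        linear feature recovers its hazard ratio exactly."""
        df = small_cohort.df.dropna(subset=["hba1c"])
        contribs = contributions_frame(df, spec)
        q1, q3 = df["hba1c"].quantile([0.25, 0.75])
        c1 = contribs["hba1c"][df["hba1c"] == df["hba1c"]].to_numpy()
        gradient = np.polyfit(df["hba1c"], c1, 1)[0]
        assert math.exp(gradient) == pytest.approx(1.13, abs=1e-9)
        assert q3 > q1  # IQR well-defined on this cohort

    def test_permutation_attribution_finds_live_feature(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(size=300), "noise": rng.normal(size=300)})

        def predict(d):
            return 1 / (1 + np.exp(-d["x"]))

        gains = permutation_attribution(predict, df, ["x", "noise"], iterations=600, seed=2)
        assert gains["x"] > 90.0


def test_spec_json_round_trip(spec):
    data = json.loads(json.dumps(spec_to_json(spec)))
    again = spec_from_json(data)
    assert again.category_cuts == spec.category_cuts
    assert again.base_hazards == spec.base_hazards
    rec_out = predict_risk36(reference_record(smoking="current"), again)
    assert rec_out.risk36 == pytest.approx(1 - math.exp(-36 * 0.00048 * 1.35), abs=1e-8)


def test_invalid_spec_rejected():
    effects = (Effect("a", "a", "per_unit", 0.0, (0.1,), (0.0,)),)
    with pytest.raises(DomainError):
        RiskModelSpec(effects=effects, category_cuts=(0.3, 0.2, 0.1))
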