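"""Score one patient with the literature-coefficient risk engine.

The engine computes a log-hazard linear predictor from published hazard
ratios (age, sex, eGFR, ACR, HbA1c, ... plus literature-informed variables
like retinopathy grade and SGLT2-inhibitor use), converts it to a 36-month
risk through the stage-specific monthly base hazard, and reports a risk
category and a complexity-adjusted uncertainty interval.
"""

from dkdrisk.core_types import PatientRecord
from dkdrisk.risk_engine import default_model_spec, predict_risk36

patient = PatientRecord(
    patient_id="demo-001",
    age=67.0, sex="male", egfr=55.0, acr=48.0, hba1c=8.6,
    diabetes_duration=14.0, bmi=33.5, sbp=142.0, smoking="former",
    medication_compliance=8.0, waist_circumference=108.0,
    lit_vars={"family_history_ckd": 0, "nsaid_chronic": 0, "dr_severity": 0,
              "imd_quintile": 2, "sglt2i": 1, "ace_arb": 1, "glp1_ra": 0,
              "finerenone": 0, "statin": 1},
)

out = predict_risk36(patient, default_model_spec())
print(f"36-month kidney outcome risk: {out.risk36:.1%}")
print(f"category:                     {out.category}")
print(f"uncertainty half-width:       {out.uncertainty:.0%} of the point risk")
print(f"interval:                     [{out.interval[0]:.1%}, {out.interval[1]:.1%}]")
print("top log-hazard contributions:")
for name, value in sorted(out.contributions.items(), key=lambda kv: -abs(kv[1]))[:5]:
    print(f"  {name:22s} {value:+.3f}")
# Positive contributions raise the hazard (e.g. albuminuria, smoking);
# negative ones are protective therapies.  exp(sum) multiplies the
# stage-specific monthly base hazard.
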