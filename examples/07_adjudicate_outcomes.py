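"""Adjudicate the composite kidney outcome on a longitudinal lab series.

The composite fires at the earliest month where any criterion holds:
eGFR < 60 with >= 25% decline from baseline, ACR >= 30 mg/g sustained for
three consecutive months, ESRD, or biopsy-proven nephropathy; death and
transplant censor follow-up.
"""

from dkdrisk.outcomes import LabObservation, OutcomeRule, adjudicate

baseline_egfr, baseline_acr = 82.0, 12.0
series = [
    LabObservation(month=6, egfr=74.0, acr=18.0),
    LabObservation(month=12, egfr=68.0, acr=34.0),
    LabObservation(month=13, egfr=66.0, acr=38.0),
    LabObservation(month=14, egfr=64.0, acr=41.0),
    LabObservation(month=20, egfr=58.0, acr=45.0),
]

res = adjudicate(baseline_egfr, baseline_acr, series, OutcomeRule())
print(f"event:        {res.event}")
print(f"event month:  {res.event_month}")
print(f"criterion:    {res.criterion}")
# ACR >= 30 at months 12, 13, 14 - three consecutive months - dates the
# albuminuria event at month 14, before the eGFR criterion would fire at
# month 20 (29% decline and < 60).
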