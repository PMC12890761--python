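"""Composite kidney-outcome adjudication on longitudinal lab series.

The composite event is the earliest month at which any criterion holds:

1. eGFR drops below 60 mL/min/1.73m^2 AND has declined >= 25% from the
   index-visit baseline (both sub-conditions required);
2. albuminuria onset: ACR >= 30 mg/g sustained for >= 3 consecutive
   months (event dated at the end of the qualifying window);
3. ESRD / renal replacement therapy;
4. biopsy-proven diabetic nephropathy.

Death or transplant censors follow-up at the month of occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from ._errors import DomainError

__all__ = ["OutcomeRule", "LabObservation", "AdjudicationResult", "adjudicate"]


@dataclass(frozen=True)
class OutcomeRule:
    egfr_threshold: float = 60.0
    decline_fraction: float = 0.25
    acr_threshold: float = 30.0
    sustained_months: int = 3
    horizon: float = 36.0

    def __post_init__(self) -> None:
        for name in ("egfr_threshold", "decline_fraction", "acr_threshold",
                     "sustained_months", "horizon"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class LabObservation:
    """One follow-up measurement (month counted from the index visit)."""

    month: int
    egfr: Optional[float] = None
    acr: Optional[float] = None
    esrd: bool = False
    biopsy_dn: bool = False
    death: bool = False
    transplant: bool = False


@dataclass(frozen=True)
class AdjudicationResult:
    event: bool
    event_month: Optional[int]
    censor_reason: str  # none | death | transplant | end_of_series
    censor_month: Optional[int]
    criterion: Optional[str]  # egfr_decline | albuminuria | esrd | biopsy


def adjudicate(
    baseline_egfr: float,
    baseline_acr: Optional[float],
    series: Sequence[LabObservation],
    rule: OutcomeRule = OutcomeRule(),
) -> AdjudicationResult:
    """Adjudicate one patient's follow-up series against the composite rule.

    The series must be time-ordered; criteria are disjunctive and the
    earliest qualifying month wins.  Observations after a death or
    transplant are not consulted.
    """
    if baseline_egfr is None or baseline_egfr <= 0:
        raise DomainError("baseline eGFR must be present and positive")
    months = [obs.month for obs in series]
    if months != sorted(months) or len(set(months)) != len(months):
        raise DomainError("lab series must be strictly time-ordered")

    acr_run: list[int] = []  # consecutive months with ACR >= threshold
    for obs in series:
        if obs.death or obs.transplant:
            reason = "death" if obs.death else "transplant"
            return AdjudicationResult(False, None, reason, obs.month, None)
        if obs.esrd:
            return AdjudicationResult(True, obs.month, "none", None, "esrd")
        if obs.biopsy_dn:
            return AdjudicationResult(True, obs.month, "none", None, "biopsy")
        if obs.egfr is not None:
            declined = obs.egfr <= (1.0 - rule.decline_fraction) * baseline_egfr
            if obs.egfr < rule.egfr_threshold and declined:
                return AdjudicationResult(True, obs.month, "none", None, "egfr_decline")
        if obs.acr is not None:
            if obs.acr >= rule.acr_threshold:
                if acr_run and obs.month != acr_run[-1] + 1:
                    acr_run = []
                acr_run.append(obs.month)
                if len(acr_run) >= rule.sustained_months:
                    return AdjudicationResult(True, obs.month, "none", None, "albuminuria")
            else:
                acr_run = []
    last = series[-1].month if series else 0
    return AdjudicationResult(False, None, "end_of_series", last, None)
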