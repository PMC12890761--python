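"""Domain types, cohort CSV I/O and record validation.

A cohort is one row per patient at their index visit: demographics,
labs, comorbidities, follow-up time in whole months, and the event
indicator for the composite kidney outcome.  Missing values are empty
CSV cells (never sentinel numbers).  Literature-informed variables
(100% missing in observed registries) live in ``lit_*`` columns and are
absent until imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from ._errors import DomainError, IntegrityError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "CkdStage",
    "PatientRecord",
    "Cohort",
    "Violation",
    "ckd_stage",
    "ckd_stage_series",
    "read_cohort",
    "write_cohort",
    "validate_record",
    "LIT_VARS",
    "REQUIRED_COLUMNS",
    "NUMERIC_COLUMNS",
]


class CkdStage(str, Enum):
    """Baseline CKD stage derived from eGFR brackets.

    Boundary values belong to the better-function stage: eGFR 90 is
    ``none`` (no CKD, eGFR >= 90), 60 is ``s1_2``, and so on down to
    stage 4 (eGFR 15-29).  eGFR below 15 (pre-dialysis range; prevalent
    ESRD is an exclusion criterion) is mapped to ``s4`` so the mapping
    is total on (0, inf).
    """

    none = "none"
    s1_2 = "s1_2"
    s3a = "s3a"
    s3b = "s3b"
    s4 = "s4"


_STAGE_ORDER = [CkdStage.none, CkdStage.s1_2, CkdStage.s3a, CkdStage.s3b, CkdStage.s4]
_STAGE_LOWER_EDGES = [90.0, 60.0, 45.0, 30.0, 0.0]


def ckd_stage(egfr: float) -> CkdStage:
    """Map an eGFR value (mL/min/1.73m^2) to its CKD stage."""
    if not np.isfinite(egfr) or egfr <= 0:
        raise DomainError(f"eGFR must be positive and finite, got {egfr!r}")
    for stage, lo in zip(_STAGE_ORDER, _STAGE_LOWER_EDGES):
        if egfr >= lo:
            return stage
    raise AssertionError("unreachable")  # pragma: no cover


def ckd_stage_series(egfr: pd.Series) -> pd.Series:
    """Vectorised :func:`ckd_stage`; missing eGFR yields missing stage."""
    bins = [0.0, 15.0, 30.0, 45.0, 60.0, 90.0, np.inf]
    labels = ["s4", "s4", "s3b", "s3a", "s1_2", "none"]
    out = pd.cut(egfr, bins=bins, labels=False, right=False)
    mapped = out.map(dict(enumerate(labels)))
    return mapped.astype("object")


LIT_VARS = (
    "family_history_ckd",
    "nsaid_chronic",
    "dr_severity",
    "imd_quintile",
    "sglt2i",
    "ace_arb",
    "glp1_ra",
    "finerenone",
    "statin",
)

REQUIRED_COLUMNS = (
    "patient_id",
    "index_date",
    "age",
    "sex",
    "egfr",
    "followup_months",
    "event",
)

NUMERIC_COLUMNS = (
    "age",
    "bmi",
    "waist_circumference",
    "sbp",
    "dbp",
    "egfr",
    "acr",
    "hba1c",
    "phosphorus",
    "fgf23",
    "diabetes_duration",
    "medication_compliance",
    "followup_months",
)

_CATEGORICAL_LEVELS = {
    "sex": {"female", "male"},
    "smoking": {"never", "former", "current"},
    "censor_reason": {"none", "administrative", "death", "transplant"},
}

_BOOL_COLUMNS = ("hypertension", "cvd", "event")


@dataclass
class PatientRecord:
    """One patient's covariates at the index visit plus follow-up."""

    patient_id: str
    index_date: str = ""
    age: Optional[float] = None
    sex: Optional[str] = None
    ethnicity: Optional[str] = None
    bmi: Optional[float] = None
    waist_circumference: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    egfr: Optional[float] = None
    acr: Optional[float] = None
    hba1c: Optional[float] = None
    phosphorus: Optional[float] = None
    fgf23: Optional[float] = None
    diabetes_duration: Optional[float] = None
    smoking: Optional[str] = None
    hypertension: Optional[bool] = None
    cvd: Optional[bool] = None
    medication_compliance: Optional[float] = None
    followup_months: Optional[float] = None
    event: bool = False
    censor_reason: str = "none"
    lit_vars: dict = field(default_factory=dict)

    def stage(self) -> CkdStage:
        if self.egfr is None:
            raise DomainError(f"patient {self.patient_id}: eGFR missing, stage undefined")
        return ckd_stage(self.egfr)


@dataclass
class Cohort:
    """A set of patients with unique ids, backed by a DataFrame.

    ``provenance`` records where the rows came from: ``observed``,
    ``synthetic``, or ``imputed:<chain_id>``.
    """

    df: pd.DataFrame
    provenance: str = "observed"

    def __post_init__(self) -> None:
        if "patient_id" not in self.df.columns:
            raise SchemaError("cohort frame lacks a patient_id column")
        dup = self.df["patient_id"].duplicated()
        if dup.any():
            ids = self.df.loc[dup, "patient_id"].unique()[:5]
            raise IntegrityError(f"duplicate patient_id values: {list(ids)}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[PatientRecord]:
        """Iterate rows as typed :class:`PatientRecord` objects."""
        fields = [f for f in PatientRecord.__dataclass_fields__ if f != "lit_vars"]
        lit_cols = [c for c in self.df.columns if c.startswith("lit_")]
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            kwargs = {}
            for f in fields:
                v = d.get(f)
                if isinstance(v, float) and np.isnan(v):
                    v = None
                if v is not None:
                    kwargs[f] = v
            lit = {}
            for c in lit_cols:
                v = d[c]
                if not (isinstance(v, float) and np.isnan(v)):
                    lit[c[4:]] = v
            yield PatientRecord(lit_vars=lit, **kwargs)

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), self.provenance)


def _coerce_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Coerce raw string columns to typed ones; count unparseable cells."""
    bad = 0
    for col in NUMERIC_COLUMNS:
        if col in df.columns:
            raw = df[col]
            num = pd.to_numeric(raw, errors="coerce")
            bad += int((num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")).sum())
            df[col] = num
    for col in _BOOL_COLUMNS:
        if col in df.columns:
            mapping = {
                "true": True, "false": False, "1": True, "0": False,
                "1.0": True, "0.0": False, "yes": True, "no": False,
            }
            lowered = df[col].astype(str).str.strip().str.lower()
            vals = lowered.map(mapping)
            bad += int((vals.isna() & (lowered != "nan") & (lowered != "")).sum())
            df[col] = vals.astype("object")
    for col, levels in _CATEGORICAL_LEVELS.items():
        if col in df.columns:
            s = df[col].astype(str).str.strip().str.lower()
            ok = s.isin(levels)
            bad += int((~ok & (s != "nan") & (s != "")).sum())
            df[col] = s.where(ok, other=np.nan)
    for col in df.columns:
        if col.startswith("lit_"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df, bad


def read_cohort(path, provenance: str = "observed") -> Cohort:
    """Read a cohort CSV (UTF-8, header row) into a typed :class:`Cohort`.

    Unparseable cells become missing with a logged count; a missing
    required column raises :class:`SchemaError` and duplicate patient
    ids raise :class:`IntegrityError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path} lacks required columns: {missing}")
    df, bad = _coerce_frame(df)
    if bad:
        logger.warning("read_cohort: %d unparseable cells set to missing", bad)
    return Cohort(df, provenance=provenance)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV; missing values become empty cells."""
    cohort.df.to_csv(path, index=False, na_rep="")


@dataclass(frozen=True)
class Violation:
    """One clinical-plausibility bound violation for a record."""

    field: str
    value: float
    lower: float
    upper: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}={self.value} outside [{self.lower}, {self.upper}]"


def validate_record(record: PatientRecord, bounds: dict[str, tuple[float, float]]) -> list[Violation]:
    """Check every present value against clinical safety bounds.

    Reports, never mutates: returns an empty list iff all present
    values are in range.  ``bounds`` maps field name -> (lo, hi),
    e.g. eGFR 5-150 and HbA1c 4-20.
    """
    out: list[Violation] = []
    for name, (lo, hi) in bounds.items():
        value = getattr(record, name, None)
        if value is None:
            value = record.lit_vars.get(name)
        if value is None:
            continue
        if not (lo <= float(value) <= hi):
            out.append(Violation(name, float(value), lo, hi))
    return out
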