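"""Core domain types and cohort CSV I/O.

One row of the cohort table is one ICU stay: demographics, comorbidity
flags, worst-case vital signs over the observation window, treatment
flags, the APACHE-IV score as reported by the source system, the
in-hospital death indicator and the follow-up time (days to death or
censoring).  All times are relative to ICU admission; there are no
calendar dates anywhere (de-identified design).

Booleans are serialised as 0/1.  A missing boolean on input is read as
``False`` (unrecorded history is treated as uncoded, the usual registry
convention); missing vitals, demographics or outcome fields are "key
data" and, in strict mode, send the row to the exclusion report instead
of the cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

VITAL_CHANNELS = ("heart_rate", "sbp", "temperature", "resp_rate", "sao2")

#: column order of the cohort CSV (documented external interface)
COHORT_COLUMNS = [
    "patient_id",
    "age",
    "male",
    "hx_heart_failure",
    "hx_chronic_lung_disease",
    "hx_chronic_cardiopulmonary",
    "hx_cancer",
    "heart_rate_worst",
    "sbp_worst",
    "temp_worst",
    "resp_rate_worst",
    "sao2_worst",
    "altered_mental_status",
    "intubated",
    "vasoactive_infusion",
    "apache_iv",
    "died_in_hospital",
    "followup_days",
    "admission_dx",
    "pe_dx_hours",
]

_BOOL_FIELDS = {
    "male",
    "hx_heart_failure",
    "hx_chronic_lung_disease",
    "hx_chronic_cardiopulmonary",
    "hx_cancer",
    "altered_mental_status",
    "intubated",
    "vasoactive_infusion",
    "died_in_hospital",
}

#: fields whose absence means "missing key data" (strict-mode exclusion)
KEY_FIELDS = (
    "age",
    "male",
    "heart_rate_worst",
    "sbp_worst",
    "temp_worst",
    "resp_rate_worst",
    "sao2_worst",
    "apache_iv",
    "died_in_hospital",
    "followup_days",
    "admission_dx",
)


class SchemaError(ValueError):
    """Cohort/vitals CSV header does not match the documented schema."""


class RowError(ValueError):
    """A row could not be parsed; carries the zero-based data row index."""

    def __init__(self, row_index: int, message: str):
        super().__init__(f"row {row_index}: {message}")
        self.row_index = row_index


@dataclass
class PatientRecord:
    """One ICU stay with everything the risk scores consume."""

    patient_id: str
    age: Optional[int] = None
    male: bool = False
    hx_heart_failure: bool = False
    hx_chronic_lung_disease: bool = False
    hx_chronic_cardiopulmonary: bool = False
    hx_cancer: bool = False
    heart_rate_worst: Optional[float] = None
    sbp_worst: Optional[float] = None
    temp_worst: Optional[float] = None
    resp_rate_worst: Optional[float] = None
    sao2_worst: Optional[float] = None
    altered_mental_status: bool = False
    intubated: bool = False
    vasoactive_infusion: bool = False
    apache_iv: Optional[int] = None
    died_in_hospital: bool = False
    followup_days: Optional[float] = None
    admission_dx: Optional[str] = None
    pe_dx_hours: Optional[float] = None

    def missing_key_fields(self) -> list[str]:
        missing = []
        for name in KEY_FIELDS:
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                missing.append(name)
        return missing

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated field invariant."""
        if self.age is not None and self.age < 0:
            raise ValueError(f"{self.patient_id}: age must be >= 0, got {self.age}")
        if self.sao2_worst is not None and not (0 <= self.sao2_worst <= 100):
            raise ValueError(f"{self.patient_id}: sao2 must be in [0, 100]")
        if self.sbp_worst is not None and self.sbp_worst <= 0:
            raise ValueError(f"{self.patient_id}: sbp must be > 0")
        if self.followup_days is not None and self.followup_days < 0:
            raise ValueError(f"{self.patient_id}: followup_days must be >= 0")
        if self.apache_iv is not None and self.apache_iv < 0:
            raise ValueError(f"{self.patient_id}: apache_iv must be >= 0")


@dataclass
class VitalsObservation:
    """A raw, time-stamped vital-sign measurement."""

    patient_id: str
    minutes_from_admission: float
    channel: str
    value: float

    def validate(self) -> None:
        if self.channel not in VITAL_CHANNELS:
            raise ValueError(f"unknown vitals channel {self.channel!r}")
        if not math.isfinite(self.value):
            raise ValueError(f"{self.patient_id}: non-finite {self.channel} value")
        if self.minutes_from_admission < 0:
            raise ValueError(f"{self.patient_id}: negative observation time")


@dataclass
class ScorePanel:
    """The four scores plus risk classes for one patient."""

    patient_id: str
    pesi: int
    pesi_class: int
    spesi: int
    icu_spesi: int
    icu_spesi_class: int
    apache_iv: int


@dataclass
class Exclusion:
    patient_id: str
    reason: str


@dataclass
class CohortReadResult:
    """Retained records plus the exclusion report; together they partition
    the input rows."""

    records: list[PatientRecord] = field(default_factory=list)
    exclusions: list[Exclusion] = field(default_factory=list)


def _parse_value(name: str, raw, row_index: int):
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "":
        return None
    try:
        if name in _BOOL_FIELDS:
            return bool(int(float(text)))
        if name in ("age", "apache_iv"):
            return int(float(text))
        if name in ("patient_id", "admission_dx"):
            return text
        return float(text)
    except ValueError as exc:
        raise RowError(row_index, f"cannot parse field {name!r}: {text!r}") from exc


def read_cohort(path: str | Path, strict: bool = False) -> CohortReadResult:
    """Read a cohort CSV.

    In strict mode a row with any missing key field (sex, vitals,
    APACHE-IV, outcome, follow-up, admission diagnosis) goes to the
    exclusion report with reason ``"missing key data"`` rather than being
    dropped silently.  A malformed header raises :class:`SchemaError`;
    an unparseable numeric raises :class:`RowError` with the row index.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(frame.columns) != COHORT_COLUMNS:
        raise SchemaError(
            f"cohort header mismatch: expected {COHORT_COLUMNS}, got {list(frame.columns)}"
        )
    result = CohortReadResult()
    for i, row in enumerate(frame.itertuples(index=False)):
        values = {}
        for name, raw in zip(COHORT_COLUMNS, row):
            parsed = _parse_value(name, raw, i)
            if parsed is None and name in _BOOL_FIELDS:
                parsed = False  # unrecorded history is uncoded
            if parsed is not None:
                values[name] = parsed
        if "patient_id" not in values:
            raise RowError(i, "missing patient_id")
        record = PatientRecord(**values)
        if strict:
            missing = record.missing_key_fields()
            if missing:
                result.exclusions.append(
                    Exclusion(record.patient_id, "missing key data")
                )
                continue
        record.validate()
        result.records.append(record)
    return result


def _format_value(name: str, value):
    if value is None:
        return ""
    if name in _BOOL_FIELDS:
        return int(bool(value))
    return value


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records to CSV so that ``read_cohort`` round-trips losslessly."""
    rows = []
    for record in records:
        record.validate()
        rows.append(
            {name: _format_value(name, getattr(record, name)) for name in COHORT_COLUMNS}
        )
    frame = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    frame.to_csv(path, index=False)


VITALS_COLUMNS = ["patient_id", "minutes_from_admission", "channel", "value"]


def read_vitals(path: str | Path) -> list[VitalsObservation]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(frame.columns) != VITALS_COLUMNS:
        raise SchemaError(
            f"vitals header mismatch: expected {VITALS_COLUMNS}, got {list(frame.columns)}"
        )
    out = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            obs = VitalsObservation(
                patient_id=str(row[0]),
                minutes_from_admission=float(row[1]),
                channel=str(row[2]),
                value=float(row[3]),
            )
        except ValueError as exc:
            raise RowError(i, str(exc)) from exc
        obs.validate()
        out.append(obs)
    return out


def write_vitals(observations: Iterable[VitalsObservation], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "patient_id": o.patient_id,
                "minutes_from_admission": o.minutes_from_admission,
                "channel": o.channel,
                "value": o.value,
            }
            for o in observations
        ],
        columns=VITALS_COLUMNS,
    )
    frame.to_csv(path, index=False)


def write_exclusions(exclusions: Sequence[Exclusion], path: str | Path) -> None:
    pd.DataFrame(
        [{"patient_id": e.patient_id, "reason": e.reason} for e in exclusions],
        columns=["patient_id", "reason"],
    ).to_csv(path, index=False)
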