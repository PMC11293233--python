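"""Cohort selection: secondary-PE inclusion window and primary-PE exclusion.

A patient belongs to the secondary-PE cohort when a pulmonary-embolism
entry appears on the running diagnosis list strictly after ICU admission
and within the inclusion window (default 48 h).  A PE entry flagged as
the primary admission diagnosis, or time-stamped exactly at admission,
is treated as PE present on admission (primary PE) and does not qualify.

Separately, stays whose primary admission diagnosis is suggestive of
primary PE (thrombectomy, embolectomy, caval filter insertion, ...) are
excluded by case-insensitive substring match against a configurable
phrase blocklist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core import Exclusion, PatientRecord, SchemaError

#: admission-diagnosis phrases suggestive of primary PE (configurable default)
DEFAULT_DX_BLOCKLIST = (
    "thrombus, arterial",
    "thrombectomy",
    "embolectomy",
    "thrombosis, vascular",
    "chest pain, atypical",
    "chest pain, respiratory",
    "vena cava filter insertion",
)

#: diagnosis-text phrases identifying a pulmonary-embolism entry
DEFAULT_PE_PATTERNS = ("pulmonary embolism", "embolus, pulmonary")


@dataclass
class DiagnosisEntry:
    """One entry on the running, time-stamped active diagnosis list."""

    patient_id: str
    dx_text: str
    minutes_from_admission: float
    is_primary_admission_dx: bool = False


def is_pe_diagnosis(text: str, patterns: Sequence[str] = DEFAULT_PE_PATTERNS) -> bool:
    lowered = text.lower()
    return any(p.lower() in lowered for p in patterns)


def select_secondary_pe(
    diagnoses: Iterable[DiagnosisEntry],
    window_hours: float = 48.0,
    pe_patterns: Sequence[str] = DEFAULT_PE_PATTERNS,
) -> set[str]:
    """Ids of patients with a qualifying secondary-PE diagnosis.

    Qualifying means: a PE entry, not the primary admission diagnosis,
    with timestamp in the half-open interval (0, window_hours] from ICU
    admission.  Monotone in ``window_hours``: a larger window can only
    add patients.
    """
    if window_hours <= 0:
        raise ValueError("window_hours must be > 0")
    window_minutes = window_hours * 60.0
    selected: set[str] = set()
    for entry in diagnoses:
        if entry.is_primary_admission_dx:
            continue
        if not is_pe_diagnosis(entry.dx_text, pe_patterns):
            continue
        if 0 < entry.minutes_from_admission <= window_minutes:
            selected.add(entry.patient_id)
    return selected


def exclude_primary_pe_dx(
    records: Sequence[PatientRecord],
    blocklist: Sequence[str] = DEFAULT_DX_BLOCKLIST,
) -> tuple[list[PatientRecord], list[Exclusion]]:
    """Partition records by primary-PE-suggestive admission diagnosis.

    Returns ``(kept, excluded)``; every exclusion carries the matching
    blocklist phrase as its reason.  Matching is case-insensitive
    substring matching.
    """
    if not blocklist:
        raise ValueError("blocklist must be non-empty")
    kept: list[PatientRecord] = []
    excluded: list[Exclusion] = []
    for record in records:
        dx = (record.admission_dx or "").lower()
        match = next((p for p in blocklist if p.lower() in dx), None)
        if match is not None:
            excluded.append(
                Exclusion(record.patient_id, f"admission diagnosis matches {match!r}")
            )
        else:
            kept.append(record)
    return kept, excluded


DIAGNOSIS_COLUMNS = [
    "patient_id",
    "dx_text",
    "minutes_from_admission",
    "is_primary_admission_dx",
]


def read_diagnoses(path) -> list[DiagnosisEntry]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(frame.columns) != DIAGNOSIS_COLUMNS:
        raise SchemaError(
            f"diagnosis header mismatch: expected {DIAGNOSIS_COLUMNS}, got {list(frame.columns)}"
        )
    return [
        DiagnosisEntry(
            patient_id=str(row[0]),
            dx_text=str(row[1]),
            minutes_from_admission=float(row[2]),
            is_primary_admission_dx=bool(int(float(row[3]))),
        )
        for row in frame.itertuples(index=False)
    ]


def write_diagnoses(diagnoses: Iterable[DiagnosisEntry], path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": d.patient_id,
                "dx_text": d.dx_text,
                "minutes_from_admission": d.minutes_from_admission,
                "is_primary_admission_dx": int(d.is_primary_admission_dx),
            }
            for d in diagnoses
        ],
        columns=DIAGNOSIS_COLUMNS,
    ).to_csv(path, index=False)
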