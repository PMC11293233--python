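"""Deterministic calculators for the PESI, sPESI and ICU-sPESI scores.

PESI (Pulmonary Embolism Severity Index) sums one point per year of age
plus fixed points for ten clinical items; sPESI (simplified PESI) counts
six equally weighted binary criteria; ICU-sPESI extends sPESI with three
severity markers observable in intensive care (intubation, altered
mental status, vasoactive infusion), for a maximum of nine points.

Every comparator is applied exactly as published: heart rate >= 110/min,
respiratory rate >= 30/min, temperature < 36.0 C, SaO2 < 90%, systolic
blood pressure < 100 mmHg, and a strict age > 80 years for the
simplified scores.  APACHE-IV is consumed precomputed (it is reported by
the source critical-care system), never derived here.
"""

from __future__ import annotations

import math
from typing import Sequence

from .core import PatientRecord, ScorePanel

_REQUIRED_VITALS = (
    ("heart_rate_worst", "heart_rate"),
    ("sbp_worst", "sbp"),
    ("temp_worst", "temperature"),
    ("resp_rate_worst", "resp_rate"),
    ("sao2_worst", "sao2"),
)

#: PESI items as (label, predicate, points); age adds floor(age) on top.
PESI_ITEMS = (
    ("male sex", lambda p: p.male, 10),
    ("history of heart failure", lambda p: p.hx_heart_failure, 10),
    ("history of chronic lung disease", lambda p: p.hx_chronic_lung_disease, 10),
    ("heart rate >=110/min", lambda p: p.heart_rate_worst >= 110, 20),
    ("respiratory rate >=30/min", lambda p: p.resp_rate_worst >= 30, 20),
    ("temperature <36.0 C", lambda p: p.temp_worst < 36.0, 20),
    ("SaO2 <90%", lambda p: p.sao2_worst < 90, 20),
    ("history of cancer", lambda p: p.hx_cancer, 30),
    ("systolic BP <100 mmHg", lambda p: p.sbp_worst < 100, 30),
    ("altered mental status", lambda p: p.altered_mental_status, 60),
)

#: sPESI criteria, one point each (maximum 6).
SPESI_ITEMS = (
    ("age >80 years", lambda p: p.age > 80),
    ("history of cancer", lambda p: p.hx_cancer),
    ("chronic cardiopulmonary disease", lambda p: p.hx_chronic_cardiopulmonary),
    ("heart rate >=110/min", lambda p: p.heart_rate_worst >= 110),
    ("systolic BP <100 mmHg", lambda p: p.sbp_worst < 100),
    ("SaO2 <90%", lambda p: p.sao2_worst < 90),
)

#: ICU-sPESI additions, one point each (maximum 9 with the six above).
ICU_EXTRA_ITEMS = (
    ("intubated", lambda p: p.intubated),
    ("altered mental status", lambda p: p.altered_mental_status),
    ("vasoactive infusion", lambda p: p.vasoactive_infusion),
)


def _check_vitals(p: PatientRecord) -> None:
    for attr, channel in _REQUIRED_VITALS:
        value = getattr(p, attr)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValueError(
                f"patient {p.patient_id}: missing worst-case vital {channel!r}"
            )
    if p.age is None or p.age < 0:
        raise ValueError(f"patient {p.patient_id}: age missing or negative")


def pesi_score(p: PatientRecord) -> int:
    """PESI total: floor(age in years) + points of all triggered items."""
    _check_vitals(p)
    return int(math.floor(p.age)) + sum(
        points for _, predicate, points in PESI_ITEMS if predicate(p)
    )


def pesi_class(score: int) -> int:
    """PESI risk class I-V from the original published strata.

    <=65 -> I, 66-85 -> II, 86-105 -> III, 106-125 -> IV, >125 -> V.
    """
    if score < 0:
        raise ValueError(f"PESI score must be >= 0, got {score}")
    if score <= 65:
        return 1
    if score <= 85:
        return 2
    if score <= 105:
        return 3
    if score <= 125:
        return 4
    return 5


def spesi_score(p: PatientRecord) -> int:
    """sPESI: count of the six binary criteria met (age strictly > 80)."""
    _check_vitals(p)
    return sum(1 for _, predicate in SPESI_ITEMS if predicate(p))


def icu_spesi_score(p: PatientRecord) -> int:
    """ICU-sPESI: sPESI plus intubation, altered mental status and
    vasoactive infusion, one point each."""
    return spesi_score(p) + sum(1 for _, predicate in ICU_EXTRA_ITEMS if predicate(p))


def icu_spesi_class(score: int) -> int:
    """ICU-sPESI class: <=2 -> I (low), 3-4 -> II (intermediate),
    5-6 -> III (high), >=7 -> IV (very high)."""
    if not 0 <= score <= 9:
        raise ValueError(f"ICU-sPESI score must be in [0, 9], got {score}")
    if score <= 2:
        return 1
    if score <= 4:
        return 2
    if score <= 6:
        return 3
    return 4


def score_panel(p: PatientRecord) -> ScorePanel:
    """All four scores plus both risk classes for one patient."""
    if p.apache_iv is None:
        raise ValueError(f"patient {p.patient_id}: missing APACHE-IV score")
    pesi = pesi_score(p)
    spesi = spesi_score(p)
    icu = icu_spesi_score(p)
    return ScorePanel(
        patient_id=p.patient_id,
        pesi=pesi,
        pesi_class=pesi_class(pesi),
        spesi=spesi,
        icu_spesi=icu,
        icu_spesi_class=icu_spesi_class(icu),
        apache_iv=int(p.apache_iv),
    )


ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V"}


def score_panels(records: Sequence[PatientRecord]) -> list[ScorePanel]:
    return [score_panel(p) for p in records]
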