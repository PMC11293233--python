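"""Vital-sign preprocessing: 30-minute window medians and worst-case reduction.

The scores are computed from the most aberrant vital-sign values observed
during the stay, where "value" means the median over a 30-minute window
rather than a single raw measurement (robust to spot artifacts).  Windows
are tumbling (non-overlapping), anchored at ICU admission, and only
observations inside a configurable horizon (default: the first 48 hours,
matching the secondary-PE diagnosis window) are considered.

"Most aberrant" is one-sided per channel, in the direction of the score
cut-offs, all of which are one-sided:

* maximum window median — heart rate (cut-off >=110/min), respiratory
  rate (>=30/min);
* minimum window median — systolic blood pressure (<100 mmHg),
  temperature (<36.0 C), oxygen saturation (<90%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core import VITAL_CHANNELS, PatientRecord, VitalsObservation

#: per-channel direction of "aberrant": +1 high is worse, -1 low is worse
ABERRANT_DIRECTION = {
    "heart_rate": +1,
    "resp_rate": +1,
    "sbp": -1,
    "temperature": -1,
    "sao2": -1,
}

#: channel -> PatientRecord attribute holding its worst-case value
WORST_FIELD = {
    "heart_rate": "heart_rate_worst",
    "sbp": "sbp_worst",
    "temperature": "temp_worst",
    "resp_rate": "resp_rate_worst",
    "sao2": "sao2_worst",
}


@dataclass
class WindowSummary:
    """Median of one (patient, channel) series over one tumbling window."""

    patient_id: str
    channel: str
    window_index: int
    median_value: float
    n_obs: int


def window_medians(
    observations: Iterable[VitalsObservation],
    window_minutes: float = 30.0,
    observation_horizon_hours: float = 48.0,
) -> list[WindowSummary]:
    """Reduce raw observations to per-window medians.

    Window ``k`` covers ``[k*window_minutes, (k+1)*window_minutes)`` from
    ICU admission.  Empty windows produce no summary; the median is the
    standard sample median (mean of the middle two for even counts).
    Observations at or beyond the horizon are ignored.
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be > 0")
    observations = list(observations)
    for obs in observations:
        obs.validate()
    if not observations:
        return []
    frame = pd.DataFrame(
        {
            "patient_id": [o.patient_id for o in observations],
            "channel": [o.channel for o in observations],
            "minutes": [o.minutes_from_admission for o in observations],
            "value": [o.value for o in observations],
        }
    )
    frame = frame[frame["minutes"] < observation_horizon_hours * 60.0]
    if frame.empty:
        return []
    frame["window_index"] = (frame["minutes"] // window_minutes).astype(int)
    grouped = (
        frame.groupby(["patient_id", "channel", "window_index"])["value"]
        .agg(["median", "size"])
        .reset_index()
    )
    return [
        WindowSummary(
            patient_id=row.patient_id,
            channel=row.channel,
            window_index=int(row.window_index),
            median_value=float(row.median),
            n_obs=int(row.size),
        )
        for row in grouped.itertuples(index=False)
    ]


@dataclass
class WorstCaseVitals:
    """Per-patient worst-case values; channels never observed are absent."""

    patient_id: str
    values: dict  # channel -> worst-case window median

    @property
    def missing_channels(self) -> list[str]:
        return [c for c in VITAL_CHANNELS if c not in self.values]


def most_aberrant(summaries: Sequence[WindowSummary]) -> dict[str, WorstCaseVitals]:
    """Collapse window medians to per-patient worst-case vitals.

    Invariant to the order of windows and idempotent (re-reducing a
    single worst value returns it unchanged).  Missing channels are
    reported via :attr:`WorstCaseVitals.missing_channels`, never raised.
    """
    per_patient: dict[str, dict[str, float]] = {}
    for s in summaries:
        if s.channel not in ABERRANT_DIRECTION:
            raise ValueError(f"unknown vitals channel {s.channel!r}")
        channels = per_patient.setdefault(s.patient_id, {})
        current = channels.get(s.channel)
        if current is None:
            channels[s.channel] = s.median_value
        elif ABERRANT_DIRECTION[s.channel] > 0:
            channels[s.channel] = max(current, s.median_value)
        else:
            channels[s.channel] = min(current, s.median_value)
    return {
        pid: WorstCaseVitals(patient_id=pid, values=vals)
        for pid, vals in per_patient.items()
    }


def apply_worst_case(
    records: Sequence[PatientRecord],
    worst: dict[str, WorstCaseVitals],
) -> list[str]:
    """Fill the ``*_worst`` fields on each record in place.

    Returns the ids of patients left with at least one missing vital
    (no observation for that channel), for the caller's exclusion logic.
    """
    incomplete = []
    for record in records:
        case = worst.get(record.patient_id)
        values = case.values if case is not None else {}
        for channel, attr in WORST_FIELD.items():
            if channel in values:
                setattr(record, attr, values[channel])
        if case is None or case.missing_channels:
            incomplete.append(record.patient_id)
    return incomplete


def preprocess_vitals(
    records: Sequence[PatientRecord],
    observations: Iterable[VitalsObservation],
    window_minutes: float = 30.0,
    observation_horizon_hours: float = 48.0,
) -> list[str]:
    """Convenience: window medians -> worst case -> fill records in place."""
    summaries = window_medians(observations, window_minutes, observation_horizon_hours)
    return apply_worst_case(records, most_aberrant(summaries))
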