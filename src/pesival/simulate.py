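"""Synthetic ICU cohort generator for secondary pulmonary embolism.

Emulates the statistical structure the validation pipeline assumes, so
every downstream stage (vitals preprocessing, scoring, discrimination,
calibration, survival) is exercisable without access-controlled ICU
data:

* binary risk criteria with realistic prevalences (cancer 22.8%,
  SBP<100 54.2%, intubation 36.5%, altered mental status 40.4%,
  vasoactive infusion 19.5%, ...), positively dependent through a single
  Gaussian latent severity factor — independent criteria cannot
  reproduce the heavy upper tail of the observed score distribution;
* criterion-specific factor loadings: comorbidity items load weakly,
  vital-sign items moderately, treatment/mental-status items strongly,
  so the simplified score built only from comorbidities and vitals
  discriminates worst and the general-severity APACHE-IV score best;
* in-hospital death drawn per patient with a class-anchored probability:
  within each ICU-sPESI class the death logit is recentred so the
  realised class mortality targets the configured per-class rates
  (defaults 8.4 / 19.1 / 39.4 / 73.3%), with a residual latent-severity
  effect that gives severity-linked scores extra discrimination;
* death times from a log-normal with configurable median (default 6.2
  days) and log-scale sigma; survivors administratively censored
  (default 55 days);
* a raw vital-sign series per patient whose 30-minute window medians
  reproduce the record's worst-case values and threshold flags exactly.

A single integer seed governs all randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .core import PatientRecord, VitalsObservation
from .scores import icu_spesi_class, icu_spesi_score
from .selection import DiagnosisEntry

#: criterion marginal prevalences (fractions of the cohort)
DEFAULT_PREVALENCES = {
    "male": 0.506,
    "hx_heart_failure": 0.169,
    "hx_chronic_lung_disease": 0.286,
    "hx_chronic_cardiopulmonary": 0.427,
    "hx_cancer": 0.228,
    "hr_high": 0.334,       # heart rate >= 110/min
    "sbp_low": 0.542,       # systolic BP < 100 mmHg
    "temp_low": 0.080,      # temperature < 36.0 C
    "rr_high": 0.230,       # respiratory rate >= 30/min
    "sao2_low": 0.165,      # SaO2 < 90%
    "altered_mental_status": 0.404,
    "intubated": 0.365,
    "vasoactive_infusion": 0.195,
}

#: latent-severity factor loadings per criterion; comorbidities load
#: weakly (they barely separate survivors from non-survivors), vitals
#: moderately, treatment/mental-status markers strongly.
DEFAULT_LOADINGS = {
    "male": 0.10,
    "hx_heart_failure": 0.10,
    "hx_chronic_lung_disease": 0.10,
    "hx_chronic_cardiopulmonary": 0.12,
    "hx_cancer": 0.15,
    "hr_high": 0.40,
    "sbp_low": 0.45,
    "temp_low": 0.45,
    "rr_high": 0.40,
    "sao2_low": 0.45,
    "altered_mental_status": 0.70,
    "intubated": 0.70,
    "vasoactive_infusion": 0.70,
}

#: in-hospital mortality by ICU-sPESI class I-IV
DEFAULT_CLASS_MORTALITY = {1: 0.084, 2: 0.191, 3: 0.394, 4: 0.733}

_ADMISSION_DX = (
    ("sepsis", 0.24),
    ("pneumonia", 0.08),
    ("mi/cardiac arrest/angina", 0.09),
    ("arrhythmia", 0.06),
    ("congestive heart failure, exacerbation", 0.05),
    ("gi bleeding", 0.04),
    ("stroke/intracranial bleeding", 0.04),
    ("respiratory arrest", 0.03),
    ("postsurgical, gastrointestinal", 0.03),
    ("emphysema/bronchitis", 0.03),
    ("other", 0.31),
)


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort; defaults describe the target
    secondary-PE population."""

    n_patients: int = 1000
    prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    loadings: dict = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    class_mortality: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MORTALITY))
    latent_mortality_effect: float = 1.0  # log-odds of death per latent-severity SD, within class
    age_median: float = 66.0
    age_sd: float = 17.0          # IQR 53-76 under the normal model
    age_loading: float = 0.15
    apache_mean: float = 58.0
    apache_sd: float = 28.0
    apache_loading: float = 0.90  # corr(APACHE-IV, latent severity)
    death_time_median_days: float = 6.2
    death_time_sigma: float = 1.4  # log-normal log-scale SD
    censor_days: float = 55.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name, p in {**self.prevalences, **{f"class {k}": v for k, v in self.class_mortality.items()}}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name!r} out of [0, 1]: {p}")
        for name, lam in self.loadings.items():
            if not -1.0 < lam < 1.0:
                raise ValueError(f"loading {name!r} out of (-1, 1): {lam}")


@dataclass
class SyntheticCohort:
    """Generator output: cohort records, raw vitals series and a
    diagnosis table (including decoy patients for the selection stage)."""

    records: list[PatientRecord]
    vitals: list[VitalsObservation]
    diagnoses: list[DiagnosisEntry]
    latent_severity: np.ndarray


def _latent_binary(rng, latent, lam, prevalence):
    """Threshold model: flag = 1 iff lam*L + sqrt(1-lam^2)*eps exceeds the
    (1-p) normal quantile, giving marginal prevalence p and positive
    pairwise dependence through the shared factor."""
    if prevalence <= 0.0:
        return np.zeros(latent.shape, dtype=bool)
    if prevalence >= 1.0:
        return np.ones(latent.shape, dtype=bool)
    x = lam * latent + np.sqrt(1.0 - lam * lam) * rng.standard_normal(latent.shape)
    return x > norm.ppf(1.0 - prevalence)


def _worst_vitals(rng, flags, n):
    """Draw worst-case vitals consistent with the realised threshold flags."""
    def draw(flag, lo_true, hi_true, lo_false, hi_false):
        out = np.where(
            flag,
            rng.uniform(lo_true, hi_true, n),
            rng.uniform(lo_false, hi_false, n),
        )
        return np.round(out, 1)

    return {
        "heart_rate": draw(flags["hr_high"], 110.0, 150.0, 62.0, 109.8),
        "sbp": draw(flags["sbp_low"], 65.0, 99.8, 100.0, 160.0),
        "temperature": draw(flags["temp_low"], 34.0, 35.9, 36.0, 38.5),
        "resp_rate": draw(flags["rr_high"], 30.0, 45.0, 10.0, 29.8),
        "sao2": draw(flags["sao2_low"], 75.0, 89.8, 90.0, 100.0),
    }


def _calibrated_death_probs(latent, classes, class_mortality, gamma):
    """Per-patient death probabilities whose class-wise mean hits the
    configured class mortality while the within-class death logit still
    rises with latent severity (slope gamma)."""
    probs = np.zeros(latent.shape)
    for cls in np.unique(classes):
        mask = classes == cls
        target = class_mortality.get(int(cls))
        if target is None:
            raise ValueError(f"no mortality configured for class {cls}")
        if target <= 0.0:
            probs[mask] = 0.0
            continue
        if target >= 1.0:
            probs[mask] = 1.0
            continue
        centred = latent[mask] - latent[mask].mean()
        if gamma == 0.0 or mask.sum() == 1:
            probs[mask] = target
            continue

        def mean_gap(alpha):
            return expit(alpha + gamma * centred).mean() - target

        alpha = brentq(mean_gap, -30.0, 30.0)
        probs[mask] = expit(alpha + gamma * centred)
    return probs


# vitals-series layout: three 30-minute windows, odd observation counts so
# each window median equals the designed value exactly
_WINDOW_OBS = (3, 1, 3)


def _vitals_series(rng, patient_id, channel, worst, flag, direction):
    """Emit a small raw series whose window medians have the designed
    worst-case as their most aberrant value and never cross the score
    threshold unless the flag is set."""
    worst_window = int(rng.integers(0, 3))
    observations = []
    for w in range(3):
        if w == worst_window:
            value = worst
        else:
            # strictly less aberrant than the worst, same side of the cut-off
            frac = rng.uniform(0.2, 0.9)
            if channel == "heart_rate":
                value = worst - frac * (worst - 60.0)
            elif channel == "resp_rate":
                value = worst - frac * (worst - 10.0)
            elif channel == "sbp":
                value = worst + frac * (160.0 - worst)
            elif channel == "temperature":
                value = worst + frac * (38.5 - worst)
            else:  # sao2
                value = worst + frac * (100.0 - worst)
            value = round(value, 1)
        n_obs = _WINDOW_OBS[int(rng.integers(0, len(_WINDOW_OBS)))]
        times = np.sort(rng.uniform(w * 30.0, (w + 1) * 30.0 - 0.5, n_obs))
        jitter = 0.0 if channel == "temperature" else 0.5
        offsets = {1: (0.0,), 3: (-jitter, 0.0, jitter)}[n_obs]
        for t, off in zip(times, offsets):
            observations.append(
                VitalsObservation(
                    patient_id=patient_id,
                    minutes_from_admission=round(float(t), 1),
                    channel=channel,
                    value=round(float(value + off), 1),
                )
            )
    return observations


def generate(spec: CohortSpec, with_vitals: bool = True) -> SyntheticCohort:
    """Draw a synthetic secondary-PE cohort.

    Reproducible given ``spec.seed``; marginal criterion prevalences are
    within Monte-Carlo error of the configured values; survivors carry
    ``followup_days == spec.censor_days``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    latent = rng.standard_normal(n)

    flags = {}
    for name, prevalence in spec.prevalences.items():
        lam = spec.loadings.get(name, 0.3)
        flags[name] = _latent_binary(rng, latent, lam, prevalence)

    lam_age = spec.age_loading
    age_z = lam_age * latent + np.sqrt(1 - lam_age**2) * rng.standard_normal(n)
    age = np.clip(np.round(spec.age_median + spec.age_sd * age_z), 18, 90).astype(int)

    lam_a = spec.apache_loading
    apache_z = lam_a * latent + np.sqrt(1 - lam_a**2) * rng.standard_normal(n)
    apache = np.clip(np.round(spec.apache_mean + spec.apache_sd * apache_z), 0, 220).astype(int)

    worst = _worst_vitals(rng, flags, n)
    dx_labels = [d for d, _ in _ADMISSION_DX]
    dx_weights = np.array([w for _, w in _ADMISSION_DX])
    admission_dx = rng.choice(dx_labels, size=n, p=dx_weights / dx_weights.sum())
    pe_hours = np.round(rng.uniform(0.5, 48.0, n), 1)

    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"synth-{i:06d}",
                age=int(age[i]),
                male=bool(flags["male"][i]),
                hx_heart_failure=bool(flags["hx_heart_failure"][i]),
                hx_chronic_lung_disease=bool(flags["hx_chronic_lung_disease"][i]),
                hx_chronic_cardiopulmonary=bool(flags["hx_chronic_cardiopulmonary"][i]),
                hx_cancer=bool(flags["hx_cancer"][i]),
                heart_rate_worst=float(worst["heart_rate"][i]),
                sbp_worst=float(worst["sbp"][i]),
                temp_worst=float(worst["temperature"][i]),
                resp_rate_worst=float(worst["resp_rate"][i]),
                sao2_worst=float(worst["sao2"][i]),
                altered_mental_status=bool(flags["altered_mental_status"][i]),
                intubated=bool(flags["intubated"][i]),
                vasoactive_infusion=bool(flags["vasoactive_infusion"][i]),
                apache_iv=int(apache[i]),
                admission_dx=str(admission_dx[i]),
                pe_dx_hours=float(pe_hours[i]),
            )
        )

    classes = np.array(
        [icu_spesi_class(icu_spesi_score(r)) for r in records], dtype=int
    )
    death_probs = _calibrated_death_probs(
        latent, classes, spec.class_mortality, spec.latent_mortality_effect
    )
    died = rng.uniform(size=n) < death_probs
    death_times = np.round(
        np.exp(
            np.log(spec.death_time_median_days)
            + spec.death_time_sigma * rng.standard_normal(n)
        ),
        2,
    )
    for i, record in enumerate(records):
        record.died_in_hospital = bool(died[i])
        record.followup_days = float(death_times[i]) if died[i] else float(spec.censor_days)

    vitals: list[VitalsObservation] = []
    if with_vitals:
        flag_by_channel = {
            "heart_rate": flags["hr_high"],
            "sbp": flags["sbp_low"],
            "temperature": flags["temp_low"],
            "resp_rate": flags["rr_high"],
            "sao2": flags["sao2_low"],
        }
        for i, record in enumerate(records):
            for channel, flag in flag_by_channel.items():
                vitals.extend(
                    _vitals_series(
                        rng,
                        record.patient_id,
                        channel,
                        worst[channel][i],
                        bool(flag[i]),
                        +1 if channel in ("heart_rate", "resp_rate") else -1,
                    )
                )

    diagnoses = _diagnosis_table(rng, records)
    return SyntheticCohort(
        records=records, vitals=vitals, diagnoses=diagnoses, latent_severity=latent
    )


def _diagnosis_table(rng, records) -> list[DiagnosisEntry]:
    """Diagnosis list for the cohort plus decoy patients that the
    selection stage must reject (late PE, primary PE, no PE)."""
    diagnoses = []
    for record in records:
        diagnoses.append(
            DiagnosisEntry(
                patient_id=record.patient_id,
                dx_text=record.admission_dx or "other",
                minutes_from_admission=0.0,
                is_primary_admission_dx=True,
            )
        )
        diagnoses.append(
            DiagnosisEntry(
                patient_id=record.patient_id,
                dx_text="embolus, pulmonary",
                minutes_from_admission=float(record.pe_dx_hours) * 60.0,
                is_primary_admission_dx=False,
            )
        )
    n_decoys = max(1, len(records) // 50)
    decoy_kinds = ("late", "primary", "none")
    for j in range(n_decoys):
        pid = f"decoy-{j:04d}"
        kind = decoy_kinds[j % len(decoy_kinds)]
        if kind == "late":
            diagnoses.append(DiagnosisEntry(pid, "embolus, pulmonary", float(rng.uniform(49, 120)) * 60.0, False))
        elif kind == "primary":
            diagnoses.append(DiagnosisEntry(pid, "embolus, pulmonary", 0.0, True))
        else:
            diagnoses.append(DiagnosisEntry(pid, "sepsis", float(rng.uniform(0, 48)) * 60.0, False))
    return diagnoses


@dataclass(frozen=True)
class GroupCounts:
    """Aggregate (n, deaths) for one stratum, as printed in the source
    validation study's results tables."""

    label: str
    n: int
    deaths: int


@dataclass(frozen=True)
class WorkedFixture:
    """Published aggregate counts of the 812-patient secondary-PE cohort,
    for exact checks of the proportion/CI machinery."""

    overall: GroupCounts
    pesi_classes: tuple[GroupCounts, ...]
    spesi_points: tuple[GroupCounts, ...]
    icu_spesi_classes: tuple[GroupCounts, ...]


def worked_fixture() -> WorkedFixture:
    """Per-stratum patient and death counts of the reference cohort."""
    return WorkedFixture(
        overall=GroupCounts("all", 812, 150),
        pesi_classes=(
            GroupCounts("I", 58, 2),
            GroupCounts("II", 89, 3),
            GroupCounts("III", 90, 4),
            GroupCounts("IV", 112, 17),
            GroupCounts("V", 463, 124),
        ),
        spesi_points=(
            GroupCounts("0", 111, 10),
            GroupCounts("1", 219, 33),
            GroupCounts("2", 242, 42),
            GroupCounts("3", 176, 39),
            GroupCounts("4", 56, 22),
            GroupCounts("5", 8, 4),
        ),
        icu_spesi_classes=(
            GroupCounts("I", 367, 31),
            GroupCounts("II", 303, 58),
            GroupCounts("III", 127, 50),
            GroupCounts("IV", 15, 11),
        ),
    )
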