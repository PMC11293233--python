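import numpy as np
import pytest
from hypothesis import settings

from pesival.core import PatientRecord

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


def make_record(**overrides) -> PatientRecord:
    """A patient meeting no score criterion; override fields to trigger
    specific items."""
    base = dict(
        patient_id="p0",
        age=40,
        male=False,
        hx_heart_failure=False,
        hx_chronic_lung_disease=False,
        hx_chronic_cardiopulmonary=False,
        hx_cancer=False,
        heart_rate_worst=80.0,
        sbp_worst=120.0,
        temp_worst=37.0,
        resp_rate_worst=16.0,
        sao2_worst=98.0,
        altered_mental_status=False,
        intubated=False,
        vasoactive_infusion=False,
        apache_iv=50,
        died_in_hospital=False,
        followup_days=55.0,
        admission_dx="sepsis",
        pe_dx_hours=24.0,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(20240801)
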