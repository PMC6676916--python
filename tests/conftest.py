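import dataclasses
import datetime

import pytest

from colindic import (
    CodedEvent,
    CodeType,
    ColonoscopyExam,
    EnrollmentSpan,
    NoiseModel,
    WindowConfig,
    default_registry,
    generate_cohort,
)
from colindic.synth import kpnc_sc_profile

EXAM_DATE = datetime.date(2012, 6, 1)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def wcfg():
    return WindowConfig()


@pytest.fixture
def exam():
    return ColonoscopyExam("E1", "P1", EXAM_DATE, "KPWA")


@pytest.fixture
def full_enrollment():
    return [EnrollmentSpan("P1", datetime.date(2008, 1, 1), datetime.date(2013, 12, 31))]


def event(code, days_before, code_type=CodeType.ICD9_DX, lab_value=None, patient="P1"):
    return CodedEvent(
        patient_id=patient,
        date=EXAM_DATE - datetime.timedelta(days=days_before),
        code=code,
        code_type=code_type,
        lab_value=lab_value,
    )


@pytest.fixture(scope="session")
def noise_free_cohort(registry, wcfg):
    """Small noise-free cohort shared by closed-loop style tests."""
    profile = dataclasses.replace(
        kpnc_sc_profile(n_exams=400), missingness_rate=0.0, source_discordance=0.0
    )
    return generate_cohort(profile, NoiseModel(), registry, wcfg, seed=20260930)
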