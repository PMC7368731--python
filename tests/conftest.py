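from datetime import date

import pytest
from hypothesis import HealthCheck, settings

from pregrisk.data_model import (
    CodedEvent,
    EventSource,
    PatientRecord,
    RegistrationStatus,
    Sex,
    StudyConfig,
)
from pregrisk.synthetic import toy_codelists

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def bundle():
    return toy_codelists()


def make_woman(
    pid: str = "W1",
    birth_year: int = 1986,
    registration_date: date = date(2010, 1, 1),
    status: RegistrationStatus = RegistrationStatus.PERMANENT,
    sex: Sex = Sex.FEMALE,
) -> PatientRecord:
    return PatientRecord(pid, birth_year, sex, registration_date, status)


def make_event(
    pid: str,
    code: str,
    event_date: date,
    source: EventSource = EventSource.PRESCRIPTION,
) -> CodedEvent:
    return CodedEvent(pid, code, event_date, source)
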