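import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

import narcoscreen as ns

settings.register_profile(
    "narcoscreen",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("narcoscreen")


@pytest.fixture
def rules():
    return ns.default_ssun_rules()


@pytest.fixture
def make_record():
    """Factory for records with sensible defaults inside the study window."""

    def factory(pid="P-1", hid="H-1", drug=ns.Drug.ZOLPIDEM,
                date="2020-01-01", dose=5.0, days=7):
        if isinstance(date, str):
            date = dt.date.fromisoformat(date)
        return ns.PrescriptionRecord(
            patient_id=pid, hospital_id=hid, drug=drug, date=date,
            daily_dose_mg=dose, days_supplied=days,
        )

    return factory


@pytest.fixture(scope="session")
def small_zolpidem_dataset():
    """A small generated dataset shared by read-only tests."""
    profile = ns.preset("zolpidem_like", seed=5, n_patients=300,
                        n_hospitals=150)
    records, population = ns.generate_dataset(profile)
    return records, population
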