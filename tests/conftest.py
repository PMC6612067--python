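from datetime import date

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_visit(**kw) -> dict:
    """One row of the canonical visits frame, with overridable fields."""
    row = {
        "patient_id": "P1",
        "visit_id": "V1",
        "visit_type": "soc",
        "admission_date": pd.Timestamp("2006-03-01"),
        "discharge_date": pd.NaT,
        "cost": 100.0,
        "primary_diagnosis": "I10",
        "medications": "",
        "subsidised": True,
        "short_stay": False,
    }
    row.update(kw)
    return row


def visits_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["admission_date"] = pd.to_datetime(df["admission_date"])
    df["discharge_date"] = pd.to_datetime(df["discharge_date"])
    return df


def make_patient(**kw) -> dict:
    row = {
        "patient_id": "P1",
        "birth_date": pd.Timestamp("1970-01-01"),
        "gender": "female",
        "race": "chinese",
        "nationality": "singaporean",
        "housing_type": "flat_3room_plus",
        "death_date": pd.NaT,
    }
    row.update(kw)
    return row


def patients_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["death_date"] = pd.to_datetime(df["death_date"])
    return df


@pytest.fixture
def study_window():
    return date(2006, 1, 1), date(2013, 1, 1)


@pytest.fixture(scope="session")
def quan_mapping():
    from husegment.codes import packaged_quan_mapping

    return packaged_quan_mapping()


@pytest.fixture(scope="session")
def ccs_mapping():
    from husegment.codes import packaged_ccs_mapping

    return packaged_ccs_mapping()
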