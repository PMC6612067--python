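"""Index-visit identification, observation windows, inclusion, and metric aggregation.

Each patient's *index visit* is their first visit inside the study enrolment
window; it anchors two consecutive fixed-length observation years,
``year1 = [index, index+365d)`` and ``year2 = [index+365d, index+730d)``
(half-open, whole days, no leap-day special-casing). A visit belongs to the
window containing its admission date; boundary-spanning inpatient stays are
attributed entirely to that window, with no proration.

Per patient-year the aggregator totals billed cost over all settings, counts
inpatient admissions (short stays included), sums length of stay (LOS) over
non-short-stay admissions (same-day stays count 1 day, per-stay LOS =
discharge − admission in days with a 1-day floor), and counts SOC visits and
ED attendances. Therapy visits contribute cost only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

YEAR_DAYS = 365

AGGREGATE_COLUMNS = [
    "patient_id",
    "window",
    "cost_total",
    "admissions",
    "los_total",
    "soc_visits",
    "ed_attendances",
    "died_in_window",
    "had_admission",
    "age_at_first_visit",
]


def find_index_visits(
    visits: pd.DataFrame, study_start, study_end
) -> pd.Series:
    """Earliest admission date in ``[study_start, study_end)`` per patient.

    Patients with no qualifying visit are absent from the result.
    """
    start = pd.Timestamp(study_start)
    end = pd.Timestamp(study_end)
    adm = pd.to_datetime(visits["admission_date"])
    in_window = visits.loc[(adm >= start) & (adm < end), ["patient_id"]].assign(
        admission_date=adm[(adm >= start) & (adm < end)]
    )
    idx = in_window.groupby("patient_id")["admission_date"].min()
    idx.name = "index_date"
    return idx


def age_in_years(birth_dates: pd.Series, at_dates: pd.Series) -> pd.Series:
    """Completed calendar years between birth and reference date."""
    b = pd.to_datetime(birth_dates)
    a = pd.to_datetime(at_dates)
    years = a.dt.year - b.dt.year
    not_yet = (a.dt.month < b.dt.month) | (
        (a.dt.month == b.dt.month) & (a.dt.day < b.dt.day)
    )
    # float dtype (with NaN) when any birth date is missing, int otherwise
    return years - not_yet.astype(int)


def apply_inclusion(
    patients: pd.DataFrame, index_dates: pd.Series, min_age: int = 21
) -> pd.Index:
    """Patient ids aged ``min_age`` or older at their index date.

    Patients without a birth date are excluded with a logged count.
    """
    pat = patients.set_index("patient_id")
    candidates = index_dates.index.intersection(pat.index)
    birth = pd.to_datetime(pat.loc[candidates, "birth_date"])
    missing = birth.isna()
    if missing.any():
        logger.warning("%d patient(s) excluded for missing birth_date", int(missing.sum()))
    candidates = candidates[~missing.to_numpy()]
    ages = age_in_years(
        pat.loc[candidates, "birth_date"], index_dates.loc[candidates]
    )
    return pd.Index(candidates[(ages >= min_age).to_numpy()], name="patient_id")


def build_windows(index_dates: pd.Series) -> pd.DataFrame:
    """Tabulate the two half-open observation years anchored at each index date."""
    idx = pd.to_datetime(index_dates)
    return pd.DataFrame(
        {
            "patient_id": idx.index,
            "index_date": idx.to_numpy(),
            "year1_start": idx.to_numpy(),
            "year1_end": (idx + pd.Timedelta(days=YEAR_DAYS)).to_numpy(),
            "year2_end": (idx + pd.Timedelta(days=2 * YEAR_DAYS)).to_numpy(),
        }
    ).reset_index(drop=True)


def _stay_los(visits: pd.DataFrame) -> pd.Series:
    """Per-stay LOS in days for inpatient rows: discharge − admission, floor 1."""
    days = (
        pd.to_datetime(visits["discharge_date"]) - pd.to_datetime(visits["admission_date"])
    ).dt.days
    return days.fillna(1).clip(lower=1)


def aggregate_window(
    visits: pd.DataFrame,
    index_dates: pd.Series,
    patients: pd.DataFrame,
    which: str = "year1",
) -> pd.DataFrame:
    """Aggregate cost and utilization per patient over one observation year.

    One row is produced for every patient in ``index_dates`` (zero-filled when
    the patient has no visits in the window), except that ``year2`` rows are
    not produced for patients who died during year 1. Visits for patients
    without an index date are ignored with a logged count.
    """
    if which not in ("year1", "year2"):
        raise ValueError(f"which must be 'year1' or 'year2', got {which!r}")
    idx = pd.to_datetime(index_dates)
    pat = patients.set_index("patient_id")

    v = visits.copy()
    v["admission_date"] = pd.to_datetime(v["admission_date"])
    known = v["patient_id"].isin(idx.index)
    if (~known).any():
        logger.warning(
            "%d visit(s) for patients without an index date ignored", int((~known).sum())
        )
        v = v[known]
    v["_index"] = v["patient_id"].map(idx)
    offset = (v["admission_date"] - v["_index"]).dt.days
    lo, hi = (0, YEAR_DAYS) if which == "year1" else (YEAR_DAYS, 2 * YEAR_DAYS)
    v = v[(offset >= lo) & (offset < hi)]

    inpat = v["visit_type"] == "inpatient"
    los = _stay_los(v).where(inpat & ~v["short_stay"], 0)
    per_visit = pd.DataFrame(
        {
            "patient_id": v["patient_id"],
            "cost_total": v["cost"],
            "admissions": inpat.astype(int),
            "los_total": los.astype(int),
            "soc_visits": (v["visit_type"] == "soc").astype(int),
            "ed_attendances": (v["visit_type"] == "ed").astype(int),
        }
    )
    agg = per_visit.groupby("patient_id").sum()
    agg = agg.reindex(idx.index, fill_value=0)

    death = pd.to_datetime(pat["death_date"]) if "death_date" in pat else pd.Series(
        pd.NaT, index=pat.index
    )
    death = death.reindex(idx.index)
    death_offset = (death - idx).dt.days
    died_y1 = death.notna() & (death_offset >= 0) & (death_offset < YEAR_DAYS)
    if which == "year1":
        agg["died_in_window"] = died_y1
    else:
        agg["died_in_window"] = (
            death.notna() & (death_offset >= YEAR_DAYS) & (death_offset < 2 * YEAR_DAYS)
        )
        agg = agg[~died_y1.reindex(agg.index).fillna(False)]

    agg["had_admission"] = agg["admissions"] > 0
    birth = pd.to_datetime(pat["birth_date"]).reindex(agg.index)
    agg["age_at_first_visit"] = age_in_years(birth, idx.reindex(agg.index))
    agg = agg.reset_index().rename(columns={"index": "patient_id"})
    agg["window"] = which
    return agg[AGGREGATE_COLUMNS]
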