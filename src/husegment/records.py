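"""Domain types, validation, and CSV readers/writers for visit- and patient-level tables.

A *visit* is one healthcare encounter at the hospital — an inpatient
admission, a specialist outpatient clinic (SOC) consultation, an emergency
department (ED) attendance, or a therapy session — carrying its dates, the
billed cost, a primary diagnosis code, dispensed-medication codes, and the
subsidy and short-stay flags. A *patient* row carries the time-invariant
socio-demographics used for group profiling.

Files are plain CSV with ISO 8601 dates; the medication set is serialized as
one semicolon-delimited field so that each visit stays on one row. The
in-memory workhorse is a validated :class:`pandas.DataFrame`; the dataclasses
below give a typed row-level view used for validation semantics and small
fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VISIT_TYPES = ("inpatient", "soc", "ed", "therapy")
GENDERS = ("female", "male")
RACES = ("chinese", "indian", "malay", "others")
NATIONALITIES = ("singaporean", "foreigner")
HOUSING_TYPES = ("rental_1_2room", "flat_3room_plus", "private", "unknown")

VISIT_COLUMNS = [
    "patient_id",
    "visit_id",
    "visit_type",
    "admission_date",
    "discharge_date",
    "cost",
    "primary_diagnosis",
    "medications",
    "subsidised",
    "short_stay",
]
PATIENT_COLUMNS = [
    "patient_id",
    "birth_date",
    "gender",
    "race",
    "nationality",
    "housing_type",
    "death_date",
]

VISIT_SCHEMA_VERSION = "1"


class SchemaError(ValueError):
    """The file header does not match the documented column set."""


class RowValidationError(ValueError):
    """One or more rows violate a record invariant.

    Attributes
    ----------
    errors : list of (row_number, message)
        1-based data-row numbers (header not counted) with a description of
        the violated invariant.
    """

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        preview = "; ".join(f"row {r}: {m}" for r, m in errors[:5])
        more = "" if len(errors) <= 5 else f" (+{len(errors) - 5} more)"
        super().__init__(f"{len(errors)} invalid row(s): {preview}{more}")


@dataclass(frozen=True)
class VisitRecord:
    """One healthcare encounter."""

    patient_id: str
    visit_id: str
    visit_type: str
    admission_date: date
    discharge_date: date | None
    cost: float
    primary_diagnosis: str
    medications: frozenset[str] = field(default_factory=frozenset)
    subsidised: bool = True
    short_stay: bool = False

    def violations(self) -> list[str]:
        out = []
        if self.visit_type not in VISIT_TYPES:
            out.append(f"visit_type {self.visit_type!r} not one of {VISIT_TYPES}")
        if self.discharge_date is not None and self.discharge_date < self.admission_date:
            out.append("discharge_date precedes admission_date")
        if self.short_stay and self.visit_type != "inpatient":
            out.append("short_stay=true on a non-inpatient visit")
        if self.cost < 0 or not np.isfinite(self.cost):
            out.append("cost is negative or non-finite")
        return out


@dataclass(frozen=True)
class PatientRecord:
    """Time-invariant patient attributes used for profiling."""

    patient_id: str
    birth_date: date
    gender: str
    race: str
    nationality: str
    housing_type: str = "unknown"
    death_date: date | None = None

    def violations(self) -> list[str]:
        out = []
        if self.gender not in GENDERS:
            out.append(f"gender {self.gender!r} not one of {GENDERS}")
        if self.race not in RACES:
            out.append(f"race {self.race!r} not one of {RACES}")
        if self.nationality not in NATIONALITIES:
            out.append(f"nationality {self.nationality!r} not one of {NATIONALITIES}")
        if self.death_date is not None and self.death_date < self.birth_date:
            out.append("death_date precedes birth_date")
        return out


# ---------------------------------------------------------------------------
# frame <-> record conversion


def _meds_to_str(meds: Iterable[str]) -> str:
    return ";".join(sorted(set(meds)))


def _str_to_meds(s: str) -> frozenset[str]:
    if not s or (isinstance(s, float) and np.isnan(s)):
        return frozenset()
    return frozenset(p for p in str(s).split(";") if p)


def visits_to_frame(records: Sequence[VisitRecord]) -> pd.DataFrame:
    """Tabulate visit records into the canonical visit frame."""
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "visit_id": [r.visit_id for r in records],
            "visit_type": [r.visit_type for r in records],
            "admission_date": pd.to_datetime([r.admission_date for r in records]),
            "discharge_date": pd.to_datetime(
                [r.discharge_date for r in records], errors="coerce"
            ),
            "cost": [float(r.cost) for r in records],
            "primary_diagnosis": [r.primary_diagnosis for r in records],
            "medications": [_meds_to_str(r.medications) for r in records],
            "subsidised": [bool(r.subsidised) for r in records],
            "short_stay": [bool(r.short_stay) for r in records],
        },
        columns=VISIT_COLUMNS,
    )
    return df


def frame_to_visits(df: pd.DataFrame) -> list[VisitRecord]:
    out = []
    for row in df.itertuples(index=False):
        disch = None if pd.isna(row.discharge_date) else row.discharge_date.date()
        out.append(
            VisitRecord(
                patient_id=str(row.patient_id),
                visit_id=str(row.visit_id),
                visit_type=str(row.visit_type),
                admission_date=row.admission_date.date(),
                discharge_date=disch,
                cost=float(row.cost),
                primary_diagnosis=str(row.primary_diagnosis),
                medications=_str_to_meds(row.medications),
                subsidised=bool(row.subsidised),
                short_stay=bool(row.short_stay),
            )
        )
    return out


def patients_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "birth_date": pd.to_datetime([r.birth_date for r in records]),
            "gender": [r.gender for r in records],
            "race": [r.race for r in records],
            "nationality": [r.nationality for r in records],
            "housing_type": [r.housing_type for r in records],
            "death_date": pd.to_datetime(
                [r.death_date for r in records], errors="coerce"
            ),
        },
        columns=PATIENT_COLUMNS,
    )


def frame_to_patients(df: pd.DataFrame) -> list[PatientRecord]:
    out = []
    for row in df.itertuples(index=False):
        death = None if pd.isna(row.death_date) else row.death_date.date()
        out.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                birth_date=row.birth_date.date(),
                gender=str(row.gender),
                race=str(row.race),
                nationality=str(row.nationality),
                housing_type=str(row.housing_type),
                death_date=death,
            )
        )
    return out


# ---------------------------------------------------------------------------
# validated frame readers / writers


def _parse_bool(series: pd.Series) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "True": True, "False": False,
    }
    return series.astype(str).str.strip().map(mapping)


def validate_visits_frame(df: pd.DataFrame) -> list[tuple[int, str]]:
    """Collect (1-based row number, message) invariant violations."""
    errors: list[tuple[int, str]] = []

    def flag(mask: pd.Series, msg: str) -> None:
        for pos in np.flatnonzero(mask.to_numpy()):
            errors.append((int(pos) + 1, msg))

    flag(df["admission_date"].isna(), "unparseable or missing admission_date")
    flag(~df["visit_type"].isin(VISIT_TYPES), "visit_type outside enum")
    bad_order = df["discharge_date"].notna() & (
        df["discharge_date"] < df["admission_date"]
    )
    flag(bad_order, "discharge_date precedes admission_date")
    flag(df["cost"].isna() | (df["cost"] < 0), "cost missing or negative")
    flag(
        df["short_stay"].fillna(False) & (df["visit_type"] != "inpatient"),
        "short_stay=true on a non-inpatient visit",
    )
    flag(df["subsidised"].isna(), "unparseable subsidised flag")
    flag(df["short_stay"].isna(), "unparseable short_stay flag")
    errors.sort(key=lambda e: e[0])
    return errors


def read_visits_frame(
    path: str | Path,
    schema_version: str = VISIT_SCHEMA_VERSION,
    skip_bad_rows: bool = False,
) -> pd.DataFrame:
    """Read and validate a visits CSV into the canonical frame.

    Rows violating record invariants abort the read with a
    :class:`RowValidationError` naming each offending row, unless
    ``skip_bad_rows`` is set, in which case they are dropped with a logged
    count.
    """
    if schema_version != VISIT_SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version {schema_version!r}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in VISIT_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    df = pd.DataFrame(index=raw.index)
    df["patient_id"] = raw["patient_id"]
    df["visit_id"] = raw["visit_id"]
    df["visit_type"] = raw["visit_type"]
    df["admission_date"] = pd.to_datetime(
        raw["admission_date"], format="%Y-%m-%d", errors="coerce"
    )
    disch = raw["discharge_date"].replace("", None)
    df["discharge_date"] = pd.to_datetime(disch, format="%Y-%m-%d", errors="coerce")
    # a non-empty but unparseable discharge date is a row error, not silence
    bad_disch = (raw["discharge_date"] != "") & df["discharge_date"].isna()
    df["cost"] = pd.to_numeric(raw["cost"], errors="coerce")
    df["primary_diagnosis"] = raw["primary_diagnosis"]
    df["medications"] = raw["medications"]
    df["subsidised"] = _parse_bool(raw["subsidised"])
    df["short_stay"] = _parse_bool(raw["short_stay"])

    errors = validate_visits_frame(df)
    errors += [(int(pos) + 1, "unparseable discharge_date")
               for pos in np.flatnonzero(bad_disch.to_numpy())]
    errors.sort(key=lambda e: e[0])
    if errors:
        if not skip_bad_rows:
            raise RowValidationError(errors)
        bad_idx = sorted({r - 1 for r, _ in errors})
        logger.warning("dropping %d invalid visit row(s)", len(bad_idx))
        df = df.drop(index=df.index[bad_idx]).reset_index(drop=True)
    df["subsidised"] = df["subsidised"].astype(bool)
    df["short_stay"] = df["short_stay"].astype(bool)
    return df[VISIT_COLUMNS]


def read_visits(
    path: str | Path,
    schema_version: str = VISIT_SCHEMA_VERSION,
    skip_bad_rows: bool = False,
) -> list[VisitRecord]:
    """Read a visits CSV as a list of validated :class:`VisitRecord`."""
    return frame_to_visits(read_visits_frame(path, schema_version, skip_bad_rows))


def write_visits(
    visits: pd.DataFrame | Sequence[VisitRecord], path: str | Path
) -> None:
    df = visits if isinstance(visits, pd.DataFrame) else visits_to_frame(visits)
    out = df.copy()
    out["admission_date"] = pd.to_datetime(out["admission_date"]).dt.strftime("%Y-%m-%d")
    dd = pd.to_datetime(out["discharge_date"])
    out["discharge_date"] = dd.dt.strftime("%Y-%m-%d").where(dd.notna(), "")
    out["cost"] = out["cost"].map(lambda c: f"{c:.2f}")
    out["subsidised"] = np.where(out["subsidised"], "true", "false")
    out["short_stay"] = np.where(out["short_stay"], "true", "false")
    out[VISIT_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def read_patients_frame(path: str | Path, skip_bad_rows: bool = False) -> pd.DataFrame:
    """Read and validate a patients CSV.

    Housing-type values outside the enum degrade to ``"unknown"`` with a
    logged warning rather than failing the row.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PATIENT_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    df = pd.DataFrame(index=raw.index)
    df["patient_id"] = raw["patient_id"]
    df["birth_date"] = pd.to_datetime(raw["birth_date"], format="%Y-%m-%d", errors="coerce")
    for col in ("gender", "race", "nationality"):
        df[col] = raw[col]
    housing = raw["housing_type"]
    unknown_mask = ~housing.isin(HOUSING_TYPES)
    if unknown_mask.any():
        logger.warning(
            "%d patient row(s) with unrecognised housing_type mapped to 'unknown'",
            int(unknown_mask.sum()),
        )
    df["housing_type"] = housing.where(~unknown_mask, "unknown")
    death = raw["death_date"].replace("", None)
    df["death_date"] = pd.to_datetime(death, format="%Y-%m-%d", errors="coerce")

    errors: list[tuple[int, str]] = []
    for pos in np.flatnonzero(df["birth_date"].isna().to_numpy()):
        errors.append((int(pos) + 1, "unparseable or missing birth_date"))
    bad = df["death_date"].notna() & (df["death_date"] < df["birth_date"])
    for pos in np.flatnonzero(bad.to_numpy()):
        errors.append((int(pos) + 1, "death_date precedes birth_date"))
    for col, allowed in (("gender", GENDERS), ("race", RACES), ("nationality", NATIONALITIES)):
        for pos in np.flatnonzero((~df[col].isin(allowed)).to_numpy()):
            errors.append((int(pos) + 1, f"{col} outside enum"))
    errors.sort(key=lambda e: e[0])
    if errors:
        if not skip_bad_rows:
            raise RowValidationError(errors)
        bad_idx = sorted({r - 1 for r, _ in errors})
        logger.warning("dropping %d invalid patient row(s)", len(bad_idx))
        df = df.drop(index=df.index[bad_idx]).reset_index(drop=True)
    return df[PATIENT_COLUMNS]


def read_patients(path: str | Path, skip_bad_rows: bool = False) -> list[PatientRecord]:
    return frame_to_patients(read_patients_frame(path, skip_bad_rows))


def write_patients(
    patients: pd.DataFrame | Sequence[PatientRecord], path: str | Path
) -> None:
    df = patients if isinstance(patients, pd.DataFrame) else patients_to_frame(patients)
    out = df.copy()
    out["birth_date"] = pd.to_datetime(out["birth_date"]).dt.strftime("%Y-%m-%d")
    dd = pd.to_datetime(out["death_date"])
    out["death_date"] = dd.dt.strftime("%Y-%m-%d").where(dd.notna(), "")
    out[PATIENT_COLUMNS].to_csv(path, index=False, lineterminator="\n")
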