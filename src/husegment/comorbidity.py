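"""Charlson comorbidity index (Quan adaptation), polypharmacy score, and CCS grouping.

The CCMI maps each primary diagnosis code to at most one of 17 comorbidity
categories and sums the category weights over *distinct* categories, so code
multiplicity is irrelevant. Within a mild/severe hierarchy pair (mild vs
moderate/severe liver disease, diabetes without vs with chronic complication,
any malignancy vs metastatic solid tumour) only the severe member scores.

The polypharmacy score (PPS) is the highest number of unique dispensed
medications the patient ever received in a single visit. CCS grouping maps
each visit's primary diagnosis to a reporting category; unmapped codes fall
into the "Residual codes; unclassified" category.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .codes import UNCLASSIFIED, CodeMapping


@dataclass(frozen=True)
class ComorbidityProfile:
    patient_id: str
    ccmi: int
    pps: int
    conditions: frozenset[str]


def _resolve_hierarchy(categories: set[str], mapping: CodeMapping) -> set[str]:
    scoring = set(categories)
    for mild, severe in mapping.hierarchy.items():
        if mild in scoring and severe in scoring:
            scoring.discard(mild)
    return scoring


def compute_ccmi(dx_codes, mapping: CodeMapping) -> int:
    """Quan-adapted Charlson index for a set of diagnosis codes.

    Unmapped codes are ignored; an empty code set scores 0.
    """
    cats = {c for c in (mapping.lookup(str(code)) for code in dx_codes) if c}
    scoring = _resolve_hierarchy(cats, mapping)
    return sum(mapping.weights.get(c, 0) for c in scoring)


def compute_ccmi_frame(visits: pd.DataFrame, mapping: CodeMapping) -> pd.Series:
    """CCMI per patient from the primary diagnoses of the given visits."""
    cat = mapping.map_series(visits["primary_diagnosis"])
    df = pd.DataFrame({"patient_id": visits["patient_id"], "cat": cat}).dropna()
    df = df.drop_duplicates()
    df["w"] = df["cat"].map(mapping.weights).fillna(0)
    # hierarchy: knock out the mild member where the severe one is present
    for mild, severe in mapping.hierarchy.items():
        has_severe = df.loc[df["cat"] == severe, "patient_id"].unique()
        drop = (df["cat"] == mild) & df["patient_id"].isin(has_severe)
        df = df[~drop]
    out = df.groupby("patient_id")["w"].sum().astype(int)
    out.name = "ccmi"
    return out


def med_count(medications: pd.Series) -> pd.Series:
    """Unique dispensed-medication count per visit (semicolon-delimited field)."""
    s = medications.fillna("").astype(str)
    return s.map(lambda x: len({p for p in x.split(";") if p}))


def compute_pps(visits: pd.DataFrame) -> pd.Series:
    """Polypharmacy score per patient: max unique medications in any one visit.

    Pass all loaded visits for the "ever prescribed" reading (the default used
    by the pipeline), or a window-restricted frame for a windowed variant.
    """
    counts = pd.DataFrame(
        {"patient_id": visits["patient_id"], "n_meds": med_count(visits["medications"])}
    )
    out = counts.groupby("patient_id")["n_meds"].max().astype(int)
    out.name = "pps"
    return out


def compute_pps_one(visit_med_sets) -> int:
    """PPS for one patient's visits given as iterables of medication codes."""
    sizes = [len(set(m)) for m in visit_med_sets]
    return max(sizes, default=0)


def assign_conditions(
    visits: pd.DataFrame, ccs_mapping: CodeMapping
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CCS condition categories of the given visits' primary diagnoses.

    Returns
    -------
    patient_conditions : DataFrame [patient_id, condition]
        One row per distinct (patient, category); unmapped codes map to
        the residual/unclassified category.
    condition_visit_counts : DataFrame [patient_id, condition, visits]
        Number of visits per (patient, category), for visit-frequency
        rankings.
    """
    cat = ccs_mapping.map_series(visits["primary_diagnosis"], default=UNCLASSIFIED)
    df = pd.DataFrame({"patient_id": visits["patient_id"], "condition": cat})
    counts = (
        df.groupby(["patient_id", "condition"], as_index=False)
        .size()
        .rename(columns={"size": "visits"})
    )
    pairs = counts[["patient_id", "condition"]].copy()
    return pairs, counts


def build_profiles(
    visits_y1: pd.DataFrame,
    all_visits: pd.DataFrame,
    quan_mapping: CodeMapping,
    patient_ids: pd.Index,
) -> pd.DataFrame:
    """Per-patient comorbidity table: patient_id, ccmi, pps.

    CCMI is computed from year-1 primary diagnoses; PPS from all loaded visits
    ("ever prescribed"). Patients in ``patient_ids`` with no contributing
    visits get 0 for both.
    """
    ccmi = compute_ccmi_frame(visits_y1, quan_mapping)
    pps = compute_pps(all_visits)
    out = pd.DataFrame(index=pd.Index(patient_ids, name="patient_id"))
    out["ccmi"] = ccmi.reindex(out.index).fillna(0).astype(int)
    out["pps"] = pps.reindex(out.index).fillna(0).astype(int)
    return out.reset_index()
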