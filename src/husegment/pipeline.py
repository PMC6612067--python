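"""End-to-end orchestration: simulate/load → aggregate → score → segment → profile → model.

The pipeline ties the modules together in the order a study would run them
and records a JSON run manifest (thresholds, group sizes, seed, configuration
hash, and the fixed analysis conventions) so a run is self-describing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import comorbidity, profiles, regression, segmentation, windows
from .codes import CodeMapping, packaged_ccs_mapping, packaged_quan_mapping
from .records import write_patients, write_visits
from .segmentation import GROUPS, ThresholdSet
from .synth import CohortConfig, config_to_yaml, generate_cohort


@dataclass
class PipelineResult:
    segmentation: pd.DataFrame
    thresholds: ThresholdSet
    aggregates_y1: pd.DataFrame
    aggregates_y2: pd.DataFrame
    group_summary: pd.DataFrame
    rankings_patients: pd.DataFrame
    rankings_visits: pd.DataFrame
    common_conditions: list[str]
    fits: dict = field(default_factory=dict)
    lrts: dict = field(default_factory=dict)
    report: pd.DataFrame | None = None
    elimination_traces: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def run_analysis(
    visits: pd.DataFrame,
    patients: pd.DataFrame,
    study_start,
    study_end,
    quan_mapping: CodeMapping | None = None,
    ccs_mapping: CodeMapping | None = None,
    q: float = 0.90,
    percentile_method: str = "linear",
    alpha: float = 0.001,
    min_age: int = 21,
    fit_models: bool = True,
    elimination_criterion: str = "lrt",
) -> PipelineResult:
    """Run the full segmentation and persistence analysis on visit-level data."""
    quan_mapping = quan_mapping or packaged_quan_mapping()
    ccs_mapping = ccs_mapping or packaged_ccs_mapping()

    index_dates = windows.find_index_visits(visits, study_start, study_end)
    included = windows.apply_inclusion(patients, index_dates, min_age=min_age)
    index_dates = index_dates.loc[included]

    agg_y1 = windows.aggregate_window(visits, index_dates, patients, "year1")
    agg_y2 = windows.aggregate_window(visits, index_dates, patients, "year2")
    seg, thresholds = segmentation.segment_cohort(
        agg_y1, agg_y2, q=q, method=percentile_method
    )

    v = visits[visits["patient_id"].isin(included)].copy()
    v["admission_date"] = pd.to_datetime(v["admission_date"])
    offset = (v["admission_date"] - v["patient_id"].map(index_dates)).dt.days
    visits_y1 = v[(offset >= 0) & (offset < windows.YEAR_DAYS)]

    prof = comorbidity.build_profiles(visits_y1, v, quan_mapping, included)
    pairs, counts = comorbidity.assign_conditions(visits_y1, ccs_mapping)

    summary = profiles.summarize_groups(seg, agg_y1, prof, patients, visits_y1)
    rank_p = profiles.rank_conditions(seg, pairs, counts, "patients_ever")
    rank_v = profiles.rank_conditions(seg, pairs, counts, "visit_frequency")
    common = profiles.common_hu_conditions(rank_p)

    result = PipelineResult(
        segmentation=seg,
        thresholds=thresholds,
        aggregates_y1=agg_y1,
        aggregates_y2=agg_y2,
        group_summary=summary,
        rankings_patients=rank_p,
        rankings_visits=rank_v,
        common_conditions=common,
    )

    if fit_models:
        covariates = _build_covariates(agg_y1, prof, patients, visits_y1)
        flags = _condition_flags(pairs, common)
        d0 = regression.build_design(seg, covariates, "m0")
        fit0 = regression.fit_logistic(d0)
        d1 = regression.build_design(seg, covariates, "m1")
        fit1, d1f, trace1 = regression.backward_eliminate(
            d1, alpha=alpha, criterion=elimination_criterion
        )
        d2 = regression.build_design(
            seg, covariates, "m2", common_conditions=common, condition_flags=flags
        )
        # model 2 = model 1's surviving factors plus the condition terms;
        # only the newly added condition indicators are subject to removal,
        # which keeps model 1 nested in model 2 for the LRT
        removed1 = {t["removed"] for t in trace1}
        d2 = d2.drop_factors(removed1 & set(d2.factors))
        forced2 = {"group"} | (set(fit1.factors) & set(d2.factors))
        fit2, d2f, trace2 = regression.backward_eliminate(
            d2, alpha=alpha, forced=forced2, criterion=elimination_criterion
        )
        lrts = {
            "m1": regression.likelihood_ratio_test(fit0, fit1),
            "m2": regression.likelihood_ratio_test(fit1, fit2),
        }
        fits = {"m0": fit0, "m1": fit1, "m2": fit2}
        result.fits = fits
        result.lrts = lrts
        result.report = regression.report_models(fits, lrts)
        result.elimination_traces = {"m1": trace1, "m2": trace2}

    group_sizes = seg["group"].value_counts().reindex(GROUPS).fillna(0).astype(int)
    result.manifest = {
        "n_included": int(len(seg)),
        "thresholds": thresholds.to_dict() if thresholds else None,
        "group_sizes": {g: int(c) for g, c in group_sizes.items()},
        "conventions": {
            "observation_year_days": windows.YEAR_DAYS,
            "exceedance": "strict (> threshold)",
            "percentile_estimator": percentile_method,
            "stay_attribution": "window containing admission date, no proration",
            "short_stays": "counted in admissions, excluded from LOS",
            "same_day_nonshort_stay_los_days": 1,
            "ccmi_lookback": "year1 primary diagnoses",
            "pps_window": "all loaded visits (ever)",
            "missing_ccmi": 0,
            "elimination": {"alpha": alpha, "criterion": elimination_criterion},
            "ci_level": 0.99,
        },
    }
    return result


def _build_covariates(agg_y1, prof, patients, visits_y1) -> pd.DataFrame:
    cov = agg_y1[["patient_id", "age_at_first_visit"]].merge(
        prof, on="patient_id", how="left"
    )
    cov = cov.merge(
        patients[["patient_id", "gender", "race", "nationality", "housing_type"]],
        on="patient_id",
        how="left",
    )
    tier = profiles.treatment_tier(visits_y1)
    cov["treatment_tier"] = (
        cov["patient_id"].map(tier).fillna("subsidised_only")
    )
    return cov


def _condition_flags(pairs: pd.DataFrame, conditions: list[str]) -> pd.DataFrame:
    flags = (
        pairs.assign(v=1)
        .pivot_table(index="patient_id", columns="condition", values="v", fill_value=0)
        .reset_index()
    )
    for c in conditions:
        if c not in flags.columns:
            flags[c] = 0
    return flags[["patient_id"] + list(conditions)]


def run_synthetic_study(
    config: CohortConfig,
    seed: int | None = None,
    outdir: str | Path | None = None,
    fit_models: bool = True,
    **kwargs,
) -> PipelineResult:
    """Generate a synthetic cohort and run the full analysis on it.

    When ``outdir`` is given, writes the input tables, all result tables, and
    the run manifest there (deterministic bytes for a fixed config and seed).
    """
    patients, visits = generate_cohort(config, seed=seed)
    result = run_analysis(
        visits,
        patients,
        config.study_start,
        config.study_end,
        fit_models=fit_models,
        **kwargs,
    )
    used_seed = config.seed if seed is None else seed
    result.manifest["seed"] = int(used_seed)
    result.manifest["config_sha256"] = hashlib.sha256(
        config_to_yaml(config).encode()
    ).hexdigest()
    if outdir is not None:
        write_outputs(result, Path(outdir), patients=patients, visits=visits)
    return result


def write_outputs(
    result: PipelineResult,
    outdir: Path,
    patients: pd.DataFrame | None = None,
    visits: pd.DataFrame | None = None,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if patients is not None:
        write_patients(patients, outdir / "patients.csv")
    if visits is not None:
        write_visits(visits, outdir / "visits.csv")

    def dump(df: pd.DataFrame, name: str, decimals: int = 4) -> None:
        df.round(decimals).to_csv(outdir / name, index=False, lineterminator="\n")

    dump(result.segmentation, "segmentation.csv")
    dump(result.aggregates_y1, "aggregates_year1.csv")
    dump(result.aggregates_y2, "aggregates_year2.csv")
    dump(result.group_summary, "group_summary.csv")
    dump(result.rankings_patients, "top_conditions_patients.csv")
    dump(result.rankings_visits, "top_conditions_visits.csv")
    if result.report is not None:
        result.report.to_csv(outdir / "persistence_models.csv", index=False, lineterminator="\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
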