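"""Group profiles: utilization summaries, socio-demographics, and condition rankings.

Per HU group the summary reports group size and share of patients, share of
total cost, median and interquartile range (first to third quartile, same
order-statistic interpolation as the thresholds) for cost, admissions, LOS,
SOC, ED, age, CCMI and PPS, categorical breakdowns (gender, race, treatment
tier, housing), and within-year death and next-year persistence counts.
Every percentage in a group column uses the group size N as denominator,
decedents included.

The *treatment tier* is derived per patient from the per-visit subsidy flags
over year 1: all subsidised → ``subsidised_only``; none → ``unsubsidised_only``;
otherwise ``both``.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import GROUPS, percentile

logger = logging.getLogger(__name__)

TREATMENT_TIERS = ("subsidised_only", "unsubsidised_only", "both")
METRICS = ["cost_total", "admissions", "los_total", "soc_visits", "ed_attendances"]


def proportion_pct(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded half-up to ``decimals`` places (table convention)."""
    if denominator == 0:
        return float("nan")
    quantum = Decimal(1).scaleb(-decimals)
    val = Decimal(float(numerator)) / Decimal(float(denominator)) * 100
    return float(val.quantize(quantum, rounding=ROUND_HALF_UP))


def treatment_tier(visits_y1: pd.DataFrame) -> pd.Series:
    """Per-patient subsidy tier from year-1 per-visit subsidised flags."""
    g = visits_y1.groupby("patient_id")["subsidised"]
    any_sub = g.any()
    all_sub = g.all()
    tier = np.where(all_sub, "subsidised_only", np.where(any_sub, "both", "unsubsidised_only"))
    out = pd.Series(tier, index=any_sub.index, name="treatment_tier")
    return out


def _median_iqr(values: pd.Series) -> tuple[float, float, float]:
    if len(values) == 0:
        return (np.nan, np.nan, np.nan)
    return (
        percentile(values, 0.50),
        percentile(values, 0.25),
        percentile(values, 0.75),
    )


def pct_of_total_cost(segmentation: pd.DataFrame, aggregates_y1: pd.DataFrame) -> pd.Series:
    """Share of total year-1 cost attributable to each group, in percent."""
    cost = aggregates_y1.set_index("patient_id")["cost_total"]
    by_group = cost.groupby(
        segmentation.set_index("patient_id")["group"].reindex(cost.index)
    ).sum()
    total = cost.sum()
    if total == 0:
        logger.warning("zero total cost: all group cost shares set to 0")
        return pd.Series(0.0, index=pd.Index(GROUPS, name="group"))
    return (by_group.reindex(GROUPS).fillna(0.0) / total * 100).rename("pct_of_total_cost")


def summarize_groups(
    segmentation: pd.DataFrame,
    aggregates_y1: pd.DataFrame,
    profiles: pd.DataFrame,
    patients: pd.DataFrame,
    visits_y1: pd.DataFrame,
) -> pd.DataFrame:
    """One summary row per HU group (plus a ``Total`` row), numeric columns.

    Groups with no members are emitted with NaN statistics.
    """
    agg = aggregates_y1.set_index("patient_id")
    seg = segmentation.set_index("patient_id")
    prof = profiles.set_index("patient_id")
    pat = patients.set_index("patient_id").reindex(seg.index)
    tier = treatment_tier(visits_y1).reindex(seg.index).fillna("subsidised_only")

    n_all = len(seg)
    cost_share = pct_of_total_cost(segmentation, aggregates_y1)

    rows = []
    for group in GROUPS + ["Total"]:
        ids = seg.index if group == "Total" else seg.index[seg["group"] == group]
        n = len(ids)
        row: dict = {"group": group, "n": n}
        row["pct_of_patients"] = proportion_pct(n, n_all) if n_all else np.nan
        row["pct_of_total_cost"] = (
            round(float(cost_share.get(group, 0.0)), 1)
            if group != "Total"
            else (100.0 if agg["cost_total"].sum() > 0 else 0.0)
        )
        sub_agg = agg.reindex(ids)
        for metric in METRICS:
            med, q1, q3 = _median_iqr(sub_agg[metric].dropna())
            key = metric.replace("_total", "").replace("_visits", "").replace("_attendances", "")
            row[f"{key}_median"], row[f"{key}_q1"], row[f"{key}_q3"] = med, q1, q3
        med, q1, q3 = _median_iqr(sub_agg["age_at_first_visit"].dropna())
        row["age_median"], row["age_q1"], row["age_q3"] = med, q1, q3
        sub_prof = prof.reindex(ids)
        for col in ("ccmi", "pps"):
            med, q1, q3 = _median_iqr(sub_prof[col].dropna())
            row[f"{col}_median"], row[f"{col}_q1"], row[f"{col}_q3"] = med, q1, q3

        for col, levels in (
            ("gender", ("female", "male")),
            ("race", ("chinese", "indian", "malay", "others")),
            ("housing_type", ("rental_1_2room", "flat_3room_plus", "private", "unknown")),
        ):
            counts = pat.loc[ids, col].value_counts() if n else pd.Series(dtype=int)
            for level in levels:
                c = int(counts.get(level, 0))
                row[f"{col}_{level}_n"] = c
                row[f"{col}_{level}_pct"] = proportion_pct(c, n) if n else np.nan
        tier_counts = tier.loc[ids].value_counts() if n else pd.Series(dtype=int)
        for level in TREATMENT_TIERS:
            c = int(tier_counts.get(level, 0))
            row[f"treatment_{level}_n"] = c
            row[f"treatment_{level}_pct"] = proportion_pct(c, n) if n else np.nan

        deaths = int(sub_agg["died_in_window"].fillna(False).sum()) if n else 0
        row["death_n"] = deaths
        row["death_pct"] = proportion_pct(deaths, n) if n else np.nan
        persisted = seg.loc[ids, "persisted"]
        p = int(persisted.fillna(False).sum()) if n else 0
        row["persistence_n"] = p
        row["persistence_pct"] = proportion_pct(p, n) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def rank_conditions(
    segmentation: pd.DataFrame,
    patient_conditions: pd.DataFrame,
    condition_visit_counts: pd.DataFrame,
    mode: str = "patients_ever",
    k: int = 5,
) -> pd.DataFrame:
    """Top-``k`` conditions per group by patients-ever or visit frequency.

    Ties at equal counts break lexicographically by condition label so the
    ranking is deterministic. Percentages use the group size as denominator.
    """
    if mode not in ("patients_ever", "visit_frequency"):
        raise ValueError(f"unknown mode {mode!r}")
    seg = segmentation.set_index("patient_id")["group"]
    group_n = seg.value_counts()
    if mode == "patients_ever":
        df = patient_conditions.drop_duplicates(["patient_id", "condition"]).copy()
        df["count"] = 1
    else:
        df = condition_visit_counts.rename(columns={"visits": "count"}).copy()
    df["group"] = df["patient_id"].map(seg)
    df = df.dropna(subset=["group"])
    counted = df.groupby(["group", "condition"], as_index=False)["count"].sum()
    counted = counted.sort_values(
        ["group", "count", "condition"], ascending=[True, False, True]
    )
    out = []
    for group in GROUPS:
        top = counted[counted["group"] == group].head(k).reset_index(drop=True)
        n = int(group_n.get(group, 0))
        for rank in range(len(top)):
            cnt = int(top.at[rank, "count"])
            out.append(
                {
                    "group": group,
                    "mode": mode,
                    "rank": rank + 1,
                    "condition": top.at[rank, "condition"],
                    "count": cnt,
                    "pct_of_group": proportion_pct(cnt, n) if n else np.nan,
                }
            )
    return pd.DataFrame(out, columns=["group", "mode", "rank", "condition", "count", "pct_of_group"])


def common_hu_conditions(rankings: pd.DataFrame) -> list[str]:
    """Deduplicated union of the groups' top-condition lists (sorted)."""
    return sorted(rankings["condition"].unique())


# ---------------------------------------------------------------------------
# bundled reference tables (large published AMC cohort) for arithmetic checks


def _data_path(name: str) -> Path:
    return Path(str(resources.files("husegment").joinpath("data", name)))


def load_reference_condition_rankings() -> pd.DataFrame:
    """Bundled top-5 condition lists per HU group from a large AMC cohort."""
    return pd.read_csv(_data_path("reference_top5_conditions.csv"), comment="#")


def load_reference_group_counts() -> pd.DataFrame:
    """Bundled group sizes with death/persistence numerators (same cohort)."""
    return pd.read_csv(_data_path("reference_group_counts.csv"), comment="#")
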