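"""High-utilizer thresholds, mutually exclusive group labels, and persistence.

A patient is a high utilizer (HU) in an observation year if they *strictly
exceed* the cohort 90th percentile of at least one of three metrics: total
billed cost, total inpatient length of stay (LOS, short stays excluded), or
specialist-outpatient-clinic (SOC) visit count. The LOS percentile is
estimated over admitted patients only; cost and SOC percentiles over the full
included cohort. The three exceedance booleans partition patients into eight
mutually exclusive labels: NonHU, Cost, LOS, SOC, LOS_SOC, Cost_LOS,
Cost_SOC, Cost_LOS_SOC.

*Persistence* is membership in any HU group in the following year, judged
against the first year's frozen thresholds; patients with no utilization in
year 2 are Non-HU there by construction, and year-1 decedents carry no
persistence label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = [
    "NonHU",
    "Cost",
    "LOS",
    "SOC",
    "LOS_SOC",
    "Cost_LOS",
    "Cost_SOC",
    "Cost_LOS_SOC",
]

_LABEL_BY_FLAGS = {
    (False, False, False): "NonHU",
    (True, False, False): "Cost",
    (False, True, False): "LOS",
    (False, False, True): "SOC",
    (False, True, True): "LOS_SOC",
    (True, True, False): "Cost_LOS",
    (True, False, True): "Cost_SOC",
    (True, True, True): "Cost_LOS_SOC",
}


@dataclass(frozen=True)
class ThresholdSet:
    """The three frozen cutoffs defining HU status in one observation year."""

    cost_p90: float
    los_p90: float | None
    soc_p90: float
    n_total: int
    n_admitted: int
    q: float = 0.90
    method: str = "linear"

    def to_dict(self) -> dict:
        return {
            "cost_p90": self.cost_p90,
            "los_p90": self.los_p90,
            "soc_p90": self.soc_p90,
            "n_total": self.n_total,
            "n_admitted": self.n_admitted,
            "q": self.q,
            "method": self.method,
        }


def percentile(values, q: float, method: str = "linear") -> float:
    """Quantile by linear interpolation between order statistics (rank
    ``1+(n-1)q``), or nearest-rank when ``method="nearest"``."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take a percentile of an empty set")
    np_method = {"linear": "linear", "nearest": "higher"}[method]
    return float(np.quantile(arr, q, method=np_method))


def compute_thresholds(
    aggregates_y1: pd.DataFrame, q: float = 0.90, method: str = "linear"
) -> ThresholdSet:
    """Estimate the three HU thresholds from year-1 aggregates.

    ``los_p90`` is computed over patients with at least one admission; when no
    patient was admitted it is None and classification ignores the LOS
    criterion (logged).
    """
    if len(aggregates_y1) == 0:
        raise ValueError("no aggregates: thresholds undefined")
    admitted = aggregates_y1.loc[aggregates_y1["had_admission"], "los_total"]
    if len(admitted) == 0:
        logger.warning("no admitted patients: LOS criterion disabled")
        los_p90 = None
    else:
        los_p90 = percentile(admitted, q, method)
    return ThresholdSet(
        cost_p90=percentile(aggregates_y1["cost_total"], q, method),
        los_p90=los_p90,
        soc_p90=percentile(aggregates_y1["soc_visits"], q, method),
        n_total=int(len(aggregates_y1)),
        n_admitted=int(len(admitted)),
        q=q,
        method=method,
    )


def classify(cost_total: float, los_total: float, soc_visits: float, t: ThresholdSet) -> str:
    """Label one patient-year; "exceeded" means strictly greater than the cutoff."""
    hc = cost_total > t.cost_p90
    hl = t.los_p90 is not None and los_total > t.los_p90
    hs = soc_visits > t.soc_p90
    return _LABEL_BY_FLAGS[(hc, hl, hs)]


def classify_frame(aggregates: pd.DataFrame, t: ThresholdSet) -> pd.Series:
    """Vectorised :func:`classify` over an aggregate frame."""
    hc = aggregates["cost_total"].to_numpy() > t.cost_p90
    if t.los_p90 is None:
        hl = np.zeros(len(aggregates), dtype=bool)
    else:
        hl = aggregates["los_total"].to_numpy() > t.los_p90
    hs = aggregates["soc_visits"].to_numpy() > t.soc_p90
    lut = np.array(
        [_LABEL_BY_FLAGS[(bool(c), bool(l), bool(s))]
         for c in (0, 1) for l in (0, 1) for s in (0, 1)]
    )
    code = (hc.astype(int) << 2) | (hl.astype(int) << 1) | hs.astype(int)
    return pd.Series(lut[code], index=aggregates.index, name="group")


def classify_persistence(
    aggregates_y2: pd.DataFrame, t_year1: ThresholdSet
) -> pd.DataFrame:
    """Persistence labels for year 2 against the frozen year-1 thresholds.

    ``aggregates_y2`` should contain one row per patient alive at the end of
    year 1 (zero-filled rows for patients with no year-2 utilization, which
    therefore come out non-persistent).
    """
    labels = classify_frame(aggregates_y2, t_year1)
    return pd.DataFrame(
        {
            "patient_id": aggregates_y2["patient_id"].to_numpy(),
            "persisted": (labels != "NonHU").to_numpy(),
        }
    )


def segment_cohort(
    aggregates_y1: pd.DataFrame,
    aggregates_y2: pd.DataFrame,
    q: float = 0.90,
    method: str = "linear",
) -> tuple[pd.DataFrame, ThresholdSet]:
    """Full segmentation: thresholds, year-1 labels, and persistence.

    Returns one row per included patient — ``patient_id, group, persisted`` —
    where ``persisted`` is nullable-boolean, NA for patients who died during
    year 1 (they have no year-2 row).
    """
    for name, df in (("year1", aggregates_y1), ("year2", aggregates_y2)):
        if df["patient_id"].duplicated().any():
            raise ValueError(f"duplicate patient rows in {name} aggregates")
    if len(aggregates_y1) == 0:
        empty = pd.DataFrame(columns=["patient_id", "group", "persisted"])
        return empty, None
    t = compute_thresholds(aggregates_y1, q=q, method=method)
    seg = pd.DataFrame(
        {
            "patient_id": aggregates_y1["patient_id"].to_numpy(),
            "group": classify_frame(aggregates_y1, t).to_numpy(),
        }
    )
    pers = classify_persistence(aggregates_y2, t).set_index("patient_id")["persisted"]
    seg["persisted"] = (
        seg["patient_id"].map(pers).astype("boolean")
    )
    return seg, t
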