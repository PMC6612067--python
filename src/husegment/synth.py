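"""Synthetic hospital-administrative cohort generator.

Real visit-level administrative data of the kind this pipeline analyses
cannot be shared, so the generator produces patient and visit tables with the
statistical structure the analysis assumes: a small admitted fraction with
heavy-tailed length of stay, right-skewed per-patient annual cost,
archetype-specific diagnosis pools, within-year mortality, and year-to-year
persistence correlation.

Each patient draws an *archetype* (a utilization phenotype: routine low use,
cardiac one-off, frail elderly multimorbid, psychiatric long stay, high-SOC
ambulatory) and a patient-level *frailty* multiplier shared across both
observation years. Event counts per setting and year are Poisson given
rate × frailty with gamma-distributed frailty of mean 1, i.e. marginally
negative binomial; the shared frailty induces both overdispersion and
cross-year persistence. The gamma shape is chosen so the standard deviation
of log-frailty equals the archetype's ``frailty_sd``.

Lengths of stay are discretised log-normal with a 1-day floor; inpatient cost
scales with LOS^0.8 so long stays are expensive; deaths are a single
Bernoulli draw within year 1, with the death date uniform in the year and all
later visits truncated. Identical (config, seed) pairs produce byte-identical
output tables.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from datetime import date

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import polygamma

from .records import PATIENT_COLUMNS, VISIT_COLUMNS

#: exponent coupling inpatient cost to length of stay
COST_LOS_POWER = 0.8


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class ArchetypeSpec:
    """Generative parameters of one utilization phenotype.

    Rates are mean events per patient-year before the frailty multiplier;
    ``los_log_mean``/``los_log_sd`` parameterise the per-admission log-normal
    LOS (days); ``cost_log_mean``/``cost_log_sd`` the per-ambulatory-visit
    log-normal billed cost (S$); ``inpatient_cost_factor`` scales an
    admission's bill relative to an ambulatory visit before the LOS coupling.
    ``frailty_sd`` is the standard deviation of log-frailty; ``year2_rate_scale``
    multiplies all year-2 rates (used to plant persistence effects).

    ``year2_activity`` is the probability that the archetype's utilization
    process is still active in year 2; with probability 1 − year2_activity
    the patient's year-2 rates drop to a dormant fraction of their year-1
    rates (the config's ``dormant_rate_factor``). This models episodic care —
    an acute event resolving, a pregnancy ending — and is what makes most
    high utilizers regress to the mean rather than persist.
    """

    name: str
    mix_weight: float
    admission_rate: float
    los_log_mean: float
    los_log_sd: float
    soc_rate: float
    ed_rate: float
    therapy_rate: float
    cost_log_mean: float
    cost_log_sd: float
    inpatient_cost_factor: float
    dx_pool: list[tuple[str, float]]
    med_count_range: tuple[int, int]
    death_hazard_year1: float
    frailty_sd: float
    age_mean: float
    age_sd: float
    p_female: float
    year2_rate_scale: float = 1.0
    year2_activity: float = 1.0

    def validate(self) -> None:
        rates = (self.admission_rate, self.soc_rate, self.ed_rate, self.therapy_rate)
        if any(r < 0 for r in rates):
            raise ConfigError(f"{self.name}: negative rate")
        if not 0 <= self.death_hazard_year1 <= 1:
            raise ConfigError(f"{self.name}: death_hazard_year1 outside [0,1]")
        if not 0 <= self.p_female <= 1:
            raise ConfigError(f"{self.name}: p_female outside [0,1]")
        if self.frailty_sd < 0 or self.year2_rate_scale <= 0:
            raise ConfigError(f"{self.name}: invalid frailty_sd or year2_rate_scale")
        if not 0 <= self.year2_activity <= 1:
            raise ConfigError(f"{self.name}: year2_activity outside [0,1]")
        if not self.dx_pool:
            raise ConfigError(f"{self.name}: empty dx_pool")
        lo, hi = self.med_count_range
        if lo < 0 or hi < lo:
            raise ConfigError(f"{self.name}: bad med_count_range")


@dataclass
class CohortConfig:
    n_patients: int
    study_start: date
    study_end: date
    archetypes: list[ArchetypeSpec]
    seed: int = 0
    short_stay_frac: float = 0.15
    race_probs: dict[str, float] = field(
        default_factory=lambda: {
            "chinese": 0.58, "indian": 0.13, "malay": 0.12, "others": 0.17,
        }
    )
    nationality_probs: dict[str, float] = field(
        default_factory=lambda: {"singaporean": 0.80, "foreigner": 0.20}
    )
    housing_probs: dict[str, float] = field(
        default_factory=lambda: {
            "rental_1_2room": 0.026,
            "flat_3room_plus": 0.633,
            "private": 0.118,
            "unknown": 0.223,
        }
    )
    subsidy_tier_probs: tuple[float, float, float] = (0.65, 0.15, 0.20)
    p_subsidised_mixed: float = 0.6
    dormant_rate_factor: float = 0.15

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not self.archetypes:
            raise ConfigError("at least one archetype is required")
        if pd.Timestamp(self.study_start) >= pd.Timestamp(self.study_end):
            raise ConfigError("study_start must precede study_end")
        total = sum(a.mix_weight for a in self.archetypes)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"mix_weights sum to {total}, expected 1")
        if not 0 <= self.short_stay_frac <= 1:
            raise ConfigError("short_stay_frac outside [0,1]")
        for a in self.archetypes:
            a.validate()


def default_archetypes() -> list[ArchetypeSpec]:
    """The packaged archetype mix: one dominant low-use phenotype plus four
    clinically motivated heavy-use phenotypes."""
    return [
        ArchetypeSpec(
            name="routine_low_use",
            mix_weight=0.787,
            admission_rate=0.06,
            los_log_mean=1.0,
            los_log_sd=0.6,
            soc_rate=1.2,
            ed_rate=0.7,
            therapy_rate=0.2,
            cost_log_mean=5.8,
            cost_log_sd=1.0,
            inpatient_cost_factor=8.0,
            dx_pool=[
                ("S00.1", 2.0), ("J06.9", 2.0), ("S93.4", 1.5), ("K52.9", 1.2),
                ("S61.0", 1.0), ("I10", 0.8), ("K29.7", 0.8), ("S52.5", 0.7),
                ("S72.0", 0.4), ("N39.0", 0.4), ("J18.9", 0.3), ("S06.0", 0.3),
                ("H57.1", 0.3), ("T24.0", 0.3),
            ],
            med_count_range=(0, 3),
            death_hazard_year1=0.012,
            frailty_sd=0.9,
            age_mean=38.0,
            age_sd=16.0,
            p_female=0.42,
            year2_activity=1.0,
        ),
        ArchetypeSpec(
            name="cardiac_one_off",
            mix_weight=0.05,
            admission_rate=1.1,
            los_log_mean=1.9,
            los_log_sd=0.5,
            soc_rate=2.5,
            ed_rate=1.0,
            therapy_rate=0.2,
            cost_log_mean=6.0,
            cost_log_sd=0.8,
            inpatient_cost_factor=6.0,
            dx_pool=[
                ("I21.0", 3.0), ("I25.1", 3.0), ("I10", 1.5), ("I63.9", 1.0),
                ("E11.9", 0.8), ("J18.9", 0.5), ("S72.0", 0.5), ("N39.0", 0.4),
            ],
            med_count_range=(4, 10),
            death_hazard_year1=0.08,
            frailty_sd=0.6,
            age_mean=57.0,
            age_sd=13.0,
            p_female=0.33,
            year2_activity=0.15,
        ),
        ArchetypeSpec(
            name="frail_elderly_multimorbid",
            mix_weight=0.04,
            admission_rate=2.3,
            los_log_mean=2.4,
            los_log_sd=0.7,
            soc_rate=3.5,
            ed_rate=1.6,
            therapy_rate=0.5,
            cost_log_mean=6.0,
            cost_log_sd=0.8,
            inpatient_cost_factor=5.0,
            dx_pool=[
                ("I63.9", 2.0), ("J18.9", 2.0), ("N39.0", 1.5), ("I25.1", 1.2),
                ("I10", 1.2), ("I21.0", 1.0), ("I50.0", 1.0), ("A41.9", 0.8),
                ("N18.5", 0.8), ("E11.2", 0.7), ("F03", 0.5), ("C78.0", 0.3),
            ],
            med_count_range=(8, 16),
            death_hazard_year1=0.20,
            frailty_sd=0.6,
            age_mean=72.0,
            age_sd=10.0,
            p_female=0.48,
            year2_activity=0.50,
        ),
        ArchetypeSpec(
            name="psychiatric_long_stay",
            mix_weight=0.025,
            admission_rate=1.0,
            los_log_mean=3.5,
            los_log_sd=0.5,
            soc_rate=3.0,
            ed_rate=1.0,
            therapy_rate=0.6,
            cost_log_mean=5.6,
            cost_log_sd=0.7,
            inpatient_cost_factor=1.2,
            dx_pool=[
                ("F32.1", 3.0), ("F20.0", 2.0), ("F31.3", 1.0), ("X99", 0.6),
                ("S00.1", 0.5), ("S06.0", 0.4), ("J18.9", 0.4), ("H57.1", 0.3),
                ("T24.0", 0.3),
            ],
            med_count_range=(2, 5),
            death_hazard_year1=0.005,
            frailty_sd=0.5,
            age_mean=34.0,
            age_sd=11.0,
            p_female=0.50,
            year2_activity=0.45,
        ),
        ArchetypeSpec(
            name="high_soc_ambulatory",
            mix_weight=0.098,
            admission_rate=0.15,
            los_log_mean=1.4,
            los_log_sd=0.6,
            soc_rate=9.0,
            ed_rate=0.3,
            therapy_rate=0.4,
            cost_log_mean=6.0,
            cost_log_sd=0.9,
            inpatient_cost_factor=10.0,
            dx_pool=[
                ("Z34.0", 2.5), ("H25.1", 1.5), ("S52.5", 1.3), ("C50.9", 1.0),
                ("O75.9", 1.0), ("K29.7", 0.9), ("N97.9", 0.8), ("I10", 0.8),
                ("E11.9", 0.5), ("F32.1", 0.3),
            ],
            med_count_range=(2, 6),
            death_hazard_year1=0.005,
            frailty_sd=0.7,
            age_mean=40.0,
            age_sd=14.0,
            p_female=0.62,
            year2_activity=0.40,
        ),
    ]


def default_config(n_patients: int = 20_000, seed: int = 0) -> CohortConfig:
    return CohortConfig(
        n_patients=n_patients,
        study_start=date(2006, 1, 1),
        study_end=date(2013, 1, 1),
        archetypes=default_archetypes(),
        seed=seed,
    )


def config_to_yaml(config: CohortConfig) -> str:
    d = asdict(config)
    d["study_start"] = str(config.study_start)
    d["study_end"] = str(config.study_end)
    for a in d["archetypes"]:
        a["dx_pool"] = [[c, float(w)] for c, w in a["dx_pool"]]
        a["med_count_range"] = list(a["med_count_range"])
    d["subsidy_tier_probs"] = list(d["subsidy_tier_probs"])
    return yaml.safe_dump(d, sort_keys=True)


def config_from_yaml(text: str) -> CohortConfig:
    d = yaml.safe_load(text)
    archetypes = []
    for a in d.pop("archetypes"):
        a["dx_pool"] = [(c, float(w)) for c, w in a["dx_pool"]]
        a["med_count_range"] = tuple(a["med_count_range"])
        archetypes.append(ArchetypeSpec(**a))
    d["study_start"] = pd.Timestamp(d["study_start"]).date()
    d["study_end"] = pd.Timestamp(d["study_end"]).date()
    if "subsidy_tier_probs" in d:
        d["subsidy_tier_probs"] = tuple(d["subsidy_tier_probs"])
    return CohortConfig(archetypes=archetypes, **d)


def plant_persistence(
    config: CohortConfig, odds_multipliers: dict[str, float]
) -> CohortConfig:
    """Return a config whose year-2 rates are inflated per archetype.

    A multiplier of 1 leaves year 2 distributed exactly as year 1; larger
    multipliers monotonically raise (and smaller ones lower) the archetype's
    odds of re-qualifying as a high utilizer against the frozen year-1
    thresholds. The mapping from multiplier to threshold-exceedance odds is
    monotone but not exactly proportional — the exceedance probability
    depends on the empirical thresholds, so the multiplier is applied
    directly to the year-2 rates.
    """
    known = {a.name for a in config.archetypes}
    for name, m in odds_multipliers.items():
        if m <= 0:
            raise ConfigError(f"multiplier for {name!r} must be positive")
        if name not in known:
            raise ConfigError(f"unknown archetype {name!r}")
    out = copy.deepcopy(config)
    for a in out.archetypes:
        if a.name in odds_multipliers:
            a.year2_rate_scale = float(odds_multipliers[a.name])
    return out


# ---------------------------------------------------------------------------
# generation


def gamma_shape_for_log_sd(sd: float) -> float:
    """Gamma shape k with Var(log X) = sd² for X ~ Gamma(k); trigamma inverse."""
    if sd <= 0:
        return np.inf
    target = sd * sd

    def f(log_k: float) -> float:
        return float(polygamma(1, np.exp(log_k))) - target

    log_k = brentq(f, -10.0, 15.0)
    return float(np.exp(log_k))


def _sample_counts(rng, rate: np.ndarray) -> np.ndarray:
    return rng.poisson(rate)


def generate_cohort(
    config: CohortConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (patients, visits) frames for two observation years.

    ``seed`` overrides ``config.seed``. Visits are sorted by patient, date and
    visit id; rerunning with the same config and seed is byte-identical.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    arch = config.archetypes
    n_arch = len(arch)

    weights = np.array([a.mix_weight for a in arch])
    a_idx = rng.choice(n_arch, size=n, p=weights / weights.sum())

    def per_patient(attr: str) -> np.ndarray:
        vals = np.array([getattr(a, attr) for a in arch], dtype=float)
        return vals[a_idx]

    # frailty: gamma, mean 1, log-sd matching the archetype parameter
    shapes = np.array([gamma_shape_for_log_sd(a.frailty_sd) for a in arch])
    k = shapes[a_idx]
    frailty = np.where(
        np.isinf(k), 1.0, rng.gamma(np.where(np.isinf(k), 1.0, k)) / np.where(np.isinf(k), 1.0, k)
    )

    # entry (potential index) date, demographics
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    span = (end - start).days
    entry_offset = rng.integers(0, span, size=n)
    entry = start + pd.to_timedelta(entry_offset, unit="D")

    ages = np.clip(rng.normal(per_patient("age_mean"), per_patient("age_sd")), 1.0, 100.0)
    birth = entry - pd.to_timedelta(np.round(ages * 365.25).astype(int), unit="D")
    female = rng.random(n) < per_patient("p_female")

    def cat_draw(probs: dict[str, float]) -> np.ndarray:
        labels = list(probs)
        p = np.array([probs[l] for l in labels], dtype=float)
        return np.array(labels, dtype=object)[rng.choice(len(labels), size=n, p=p / p.sum())]

    race = cat_draw(config.race_probs)
    nationality = cat_draw(config.nationality_probs)
    housing = cat_draw(config.housing_probs)

    # death within year 1
    dies = rng.random(n) < per_patient("death_hazard_year1")
    death_day = rng.integers(0, 365, size=n)
    death_date = np.where(
        dies, (entry + pd.to_timedelta(death_day, unit="D")).to_numpy(), np.datetime64("NaT")
    )

    # patient-level subsidy tier
    tier = rng.choice(3, size=n, p=np.asarray(config.subsidy_tier_probs))

    patient_ids = np.array([f"P{i:07d}" for i in range(n)], dtype=object)
    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "birth_date": birth,
            "gender": np.where(female, "female", "male"),
            "race": race,
            "nationality": nationality,
            "housing_type": housing,
            "death_date": pd.to_datetime(death_date),
        },
        columns=PATIENT_COLUMNS,
    )

    # --- visit events ------------------------------------------------------
    settings = ("inpatient", "soc", "ed", "therapy")
    rate_attr = {
        "inpatient": "admission_rate",
        "soc": "soc_rate",
        "ed": "ed_rate",
        "therapy": "therapy_rate",
    }
    # year-2 episodic activity: dormant patients drop to a fraction of their
    # year-1 rates; the planted year2_rate_scale multiplies on top
    active_y2 = rng.random(n) < per_patient("year2_activity")
    y2_scale = per_patient("year2_rate_scale") * np.where(
        active_y2, 1.0, config.dormant_rate_factor
    )

    pieces = []
    for year, year_scale in ((1, np.ones(n)), (2, y2_scale)):
        for setting in settings:
            lam = per_patient(rate_attr[setting]) * frailty * year_scale
            counts = _sample_counts(rng, lam)
            total = int(counts.sum())
            if total == 0:
                continue
            owner = np.repeat(np.arange(n), counts)
            offsets = rng.integers(0, 365, size=total) + (year - 1) * 365
            pieces.append(
                pd.DataFrame(
                    {
                        "owner": owner,
                        "setting": setting,
                        "offset": offsets,
                        "year": year,
                    }
                )
            )
    if pieces:
        ev = pd.concat(pieces, ignore_index=True)
    else:
        ev = pd.DataFrame(columns=["owner", "setting", "offset", "year"])

    if len(ev):
        # anchor each patient's earliest year-1 visit at offset 0 so the entry
        # date is the index visit
        y1 = ev[ev["year"] == 1]
        if len(y1):
            first_pos = y1.groupby("owner")["offset"].idxmin()
            ev.loc[first_pos.to_numpy(), "offset"] = 0

        m = len(ev)
        owner = ev["owner"].to_numpy()
        setting = ev["setting"].to_numpy()
        offset = ev["offset"].to_numpy()

        inpat = setting == "inpatient"
        los = np.zeros(m, dtype=int)
        short = np.zeros(m, dtype=bool)
        if inpat.any():
            los_raw = rng.lognormal(
                per_patient("los_log_mean")[owner[inpat]],
                per_patient("los_log_sd")[owner[inpat]],
            )
            los[inpat] = np.maximum(1, np.round(los_raw).astype(int))
            short[inpat] = rng.random(int(inpat.sum())) < config.short_stay_frac
            los[inpat & short] = 0  # short stays are same-day

        base_cost = rng.lognormal(
            per_patient("cost_log_mean")[owner], per_patient("cost_log_sd")[owner]
        )
        cost = base_cost.copy()
        factor = per_patient("inpatient_cost_factor")[owner]
        cost[inpat & ~short] = (
            base_cost[inpat & ~short]
            * factor[inpat & ~short]
            * np.maximum(los[inpat & ~short], 1) ** COST_LOS_POWER
        )
        cost[inpat & short] = base_cost[inpat & short] * factor[inpat & short] * 0.5
        cost = np.round(cost, 2)

        # diagnoses from each archetype's pool
        dx = np.empty(m, dtype=object)
        for ai, a in enumerate(arch):
            mask = a_idx[owner] == ai
            cnt = int(mask.sum())
            if cnt == 0:
                continue
            codes = np.array([c for c, _ in a.dx_pool], dtype=object)
            w = np.array([w for _, w in a.dx_pool], dtype=float)
            dx[mask] = codes[rng.choice(len(codes), size=cnt, p=w / w.sum())]

        # medications
        med_lo = np.array([a.med_count_range[0] for a in arch])[a_idx][owner]
        med_hi = np.array([a.med_count_range[1] for a in arch])[a_idx][owner]
        n_meds = rng.integers(med_lo, med_hi + 1)
        med_codes = rng.integers(1, 201, size=int(n_meds.sum()))
        med_owner_ptr = np.repeat(np.arange(m), n_meds)
        meds = np.full(m, "", dtype=object)
        if len(med_codes):
            md = pd.DataFrame({"i": med_owner_ptr, "c": med_codes})
            joined = (
                md.drop_duplicates()
                .assign(code=lambda d: "M" + d["c"].astype(str).str.zfill(3))
                .sort_values(["i", "code"])
                .groupby("i")["code"]
                .agg(";".join)
            )
            meds[joined.index.to_numpy()] = joined.to_numpy()

        subsidised = np.where(
            tier[owner] == 0,
            True,
            np.where(tier[owner] == 1, False, rng.random(m) < config.p_subsidised_mixed),
        )

        admission = entry[owner] + pd.to_timedelta(offset, unit="D")
        discharge = pd.Series(pd.NaT, index=range(m), dtype="datetime64[ns]")
        discharge[inpat & short] = admission[inpat & short]
        discharge[inpat & ~short] = admission[inpat & ~short] + pd.to_timedelta(
            los[inpat & ~short], unit="D"
        )

        visits = pd.DataFrame(
            {
                "patient_id": patient_ids[owner],
                "visit_id": "",
                "visit_type": setting,
                "admission_date": admission,
                "discharge_date": discharge.to_numpy(),
                "cost": cost,
                "primary_diagnosis": dx,
                "medications": meds,
                "subsidised": subsidised,
                "short_stay": short,
            },
            columns=VISIT_COLUMNS,
        )

        # death truncation: drop visits admitted after the death date
        dd = patients.set_index("patient_id")["death_date"]
        vd = visits["patient_id"].map(dd)
        visits = visits[vd.isna() | (visits["admission_date"] <= vd)]

        visits = visits.sort_values(
            ["patient_id", "admission_date", "visit_type", "cost"], kind="mergesort"
        ).reset_index(drop=True)
        visits["visit_id"] = [f"V{i:08d}" for i in range(len(visits))]
    else:
        visits = pd.DataFrame(columns=VISIT_COLUMNS)
        visits = visits.astype({"cost": float, "subsidised": bool, "short_stay": bool})

    return patients, visits
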