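"""Staged logistic models of high-utilizer persistence.

Model 0 regresses next-year persistence on the year-1 HU group alone;
Model 1 adds socio-demographics (age at first visit, gender, race,
nationality, treatment tier, housing) and multi-morbidity (CCMI, PPS);
Model 2 further adds one presence indicator per common HU condition. After
each augmentation, factors not significant at the 0.1% level are removed by
backward elimination: factors (all dummy levels jointly) are tested with
likelihood-ratio tests, worst first, with the HU-group exposure always
forced. Odds ratios are reported with 99% Wald confidence intervals, plus
McFadden's pseudo-R² and likelihood-ratio tests between nested models.

Exclusions follow the persistence analysis design: patients who died in
year 1 or with missing gender/race/nationality are dropped; missing CCMI is
taken as 0; unknown housing forms its own level rather than being treated as
missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .segmentation import GROUPS

REFERENCE_LEVELS = {
    "group": "NonHU",
    "gender": "female",
    "race": "chinese",
    "nationality": "foreigner",
    "treatment_tier": "subsidised_only",
    "housing_type": "rental_1_2room",
}

M1_FACTORS = [
    "age_at_first_visit",
    "gender",
    "race",
    "nationality",
    "treatment_tier",
    "housing_type",
    "ccmi",
    "pps",
]

CONDITION_PREFIX = "cond: "


class FitError(RuntimeError):
    """Logistic fit failed (separation, collinearity, or non-convergence)."""


@dataclass
class ModelDesign:
    """Outcome, design matrix, and factor → column bookkeeping."""

    y: pd.Series
    X: pd.DataFrame  # includes 'const'
    factors: dict[str, list[str]]  # factor name -> design column names
    forced: set[str] = field(default_factory=lambda: {"group"})

    @property
    def n(self) -> int:
        return len(self.y)

    def drop_factors(self, names) -> "ModelDesign":
        names = set(names)
        cols = ["const"] + [
            c for f, cs in self.factors.items() if f not in names for c in cs
        ]
        return ModelDesign(
            y=self.y,
            X=self.X[[c for c in self.X.columns if c in cols]],
            factors={f: cs for f, cs in self.factors.items() if f not in names},
            forced=set(self.forced),
        )


@dataclass
class ModelFit:
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    loglik: float
    null_loglik: float
    or_table: pd.DataFrame  # term, level, OR, ci_low, ci_high
    factors: dict[str, list[str]]
    n: int

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def df_residual(self) -> int:
        return self.n - len(self.params)

    @property
    def mcfadden_r2(self) -> float:
        return 1.0 - self.loglik / self.null_loglik


def _dummies(series: pd.Series, factor: str, reference: str) -> pd.DataFrame:
    levels = [l for l in pd.unique(series.astype(str)) if l != reference]
    # stable, human-friendly level order
    if factor == "group":
        levels = [g for g in GROUPS if g in levels]
    else:
        levels = sorted(levels)
    out = pd.DataFrame(index=series.index)
    for level in levels:
        out[f"{factor}[{level}]"] = (series.astype(str) == level).astype(float)
    return out


def build_design(
    segmentation: pd.DataFrame,
    covariates: pd.DataFrame,
    model: str = "m0",
    common_conditions: list[str] | None = None,
    condition_flags: pd.DataFrame | None = None,
) -> ModelDesign:
    """Assemble the design for Model 0/1/2.

    ``covariates`` is patient-keyed with columns ``age_at_first_visit, gender,
    race, nationality, treatment_tier, housing_type, ccmi, pps`` (missing
    CCMI → 0 here); ``condition_flags`` is a patient × condition 0/1 frame
    used for Model 2 presence indicators.
    """
    if model not in ("m0", "m1", "m2"):
        raise ValueError(f"model must be m0/m1/m2, got {model!r}")
    df = segmentation.merge(covariates, on="patient_id", how="left")
    # exclusions: year-1 decedents (no persistence label), missing socio-demographics
    df = df[df["persisted"].notna()]
    for col in ("gender", "race", "nationality"):
        df = df[df[col].notna() & (df[col].astype(str) != "")]
    df = df.reset_index(drop=True)
    if df["patient_id"].duplicated().any():
        raise ValueError("duplicate patients in design")

    y = df["persisted"].astype(int)
    y.name = "persisted"
    X = pd.DataFrame({"const": np.ones(len(df))})
    factors: dict[str, list[str]] = {}

    dgroup = _dummies(df["group"], "group", REFERENCE_LEVELS["group"])
    X = pd.concat([X, dgroup], axis=1)
    factors["group"] = list(dgroup.columns)

    if model in ("m1", "m2"):
        df["ccmi"] = df["ccmi"].fillna(0)
        for factor in M1_FACTORS:
            if factor in ("age_at_first_visit", "ccmi", "pps"):
                X[factor] = df[factor].astype(float)
                factors[factor] = [factor]
            else:
                d = _dummies(df[factor], factor, REFERENCE_LEVELS[factor])
                X = pd.concat([X, d], axis=1)
                factors[factor] = list(d.columns)
    if model == "m2":
        if common_conditions is None or condition_flags is None:
            raise ValueError("m2 requires common_conditions and condition_flags")
        flags = condition_flags.set_index("patient_id").reindex(df["patient_id"])
        for cond in common_conditions:
            col = f"{CONDITION_PREFIX}{cond}"
            X[col] = (
                flags[cond].fillna(0).astype(float).to_numpy()
                if cond in flags.columns
                else 0.0
            )
            factors[col] = [col]
    X.index = y.index
    return ModelDesign(y=y, X=X, factors=factors)


def _null_loglik(y: np.ndarray) -> float:
    n = len(y)
    n1 = float(y.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        return 0.0
    p = n1 / n
    return n1 * np.log(p) + n0 * np.log(1 - p)


def fit_logistic(
    design: ModelDesign,
    ci_level: float = 0.99,
    start_params: pd.Series | None = None,
) -> ModelFit:
    """Maximum-likelihood logistic fit with Wald CIs on the OR scale.

    Collinear columns are dropped with a warning before fitting; separation
    or non-convergence raises :class:`FitError` naming the offending term.
    """
    y = design.y.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise FitError("outcome is constant after exclusions")
    X = design.X
    # drop collinear columns (keep 'const')
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        keep = ["const"]
        for col in X.columns:
            if col == "const":
                continue
            trial = X[keep + [col]].to_numpy()
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(col)
        dropped = [c for c in X.columns if c not in keep]
        import logging

        logging.getLogger(__name__).warning(
            "dropping collinear column(s): %s", dropped
        )
        X = X[keep]
    start = None
    if start_params is not None:
        start = np.array([start_params.get(c, 0.0) for c in X.columns])

    def _irls(start_vec):
        # IRLS with deviance tolerance; robust to the nearly flat directions
        # a quasi-separated dummy level produces
        return sm.GLM(y, X, family=sm.families.Binomial()).fit(
            maxiter=100, tol=1e-8, tol_criterion="deviance", start_params=start_vec
        )

    try:
        res = _irls(start)
        params_arr = np.asarray(res.params)
        if start is not None and (
            np.any(~np.isfinite(params_arr)) or np.abs(params_arr).max() > 30
        ):
            # a poor warm start can send IRLS off a cliff; redo cold
            res = _irls(None)
    except Exception as exc:  # statsmodels raises various numerical errors
        if start is None:
            raise FitError(f"logistic fit failed: {exc}") from exc
        try:
            res = _irls(None)
        except Exception as exc2:
            raise FitError(f"logistic fit failed: {exc2}") from exc2
    params_arr = np.asarray(res.params)
    if np.any(~np.isfinite(params_arr)) or np.any(~np.isfinite(np.asarray(res.bse))):
        worst = X.columns[int(np.argmax(~np.isfinite(params_arr)))]
        raise FitError(f"logistic fit did not converge (term {worst!r})")
    if res.deviance < 1e-6 * len(y):
        worst = X.columns[int(np.argmax(np.abs(params_arr)))]
        raise FitError(f"complete separation suspected on term {worst!r}")
    if np.abs(params_arr).max() > 15:
        import logging

        worst = X.columns[int(np.argmax(np.abs(params_arr)))]
        logging.getLogger(__name__).warning(
            "quasi-separation suspected on term %r (|coef| > 15); "
            "its OR and CI are unreliable", worst
        )

    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    rows = []
    for col in X.columns:
        if col == "const":
            continue
        b, se = params[col], bse[col]
        rows.append(
            {
                "term": col,
                "OR": float(np.exp(min(b, 700.0))),
                "ci_low": float(np.exp(min(b - z * se, 700.0))),
                "ci_high": float(np.exp(min(b + z * se, 700.0))),
            }
        )
    or_table = pd.DataFrame(rows, columns=["term", "OR", "ci_low", "ci_high"])
    return ModelFit(
        params=params,
        bse=bse,
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        loglik=float(res.llf),
        null_loglik=_null_loglik(y),
        or_table=or_table,
        factors={f: [c for c in cs if c in X.columns] for f, cs in design.factors.items()},
        n=len(y),
    )


def likelihood_ratio_test(nested: ModelFit, full: ModelFit) -> tuple[float, int, float]:
    """LRT of two nested fits: (chi2, df, p)."""
    nested_terms = set(nested.params.index)
    full_terms = set(full.params.index)
    if not nested_terms <= full_terms or nested.n != full.n:
        raise ValueError("models are not nested on the same observations")
    chi2 = 2.0 * (full.loglik - nested.loglik)
    chi2 = max(chi2, 0.0)
    df = len(full.params) - len(nested.params)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


def backward_eliminate(
    design: ModelDesign,
    alpha: float = 0.001,
    forced: set[str] | None = None,
    criterion: str = "lrt",
) -> tuple[ModelFit, ModelDesign, list[dict]]:
    """Iterative factor-level backward elimination at significance ``alpha``.

    Each removable factor (all of its dummy columns jointly) is tested by a
    likelihood-ratio test against the current model (``criterion="wald"``
    switches to a joint Wald chi-square); the factor with the largest
    p ≥ alpha is removed and the model refitted, until every remaining
    removable factor is significant. The forced factors (by default the
    HU-group exposure) are never removed.
    """
    forced = set(design.forced if forced is None else forced)
    current = design
    fit = fit_logistic(current)
    trace: list[dict] = []
    while True:
        removable = [f for f in current.factors if f not in forced]
        if not removable:
            break
        pvals = {}
        for f in removable:
            if criterion == "lrt":
                sub_fit = fit_logistic(
                    current.drop_factors([f]), start_params=fit.params
                )
                chi2, df, p = likelihood_ratio_test(sub_fit, fit)
            else:
                cols = [c for c in current.factors[f] if c in fit.params.index]
                b = fit.params[cols].to_numpy()
                # joint Wald: b' V^-1 b with V the fitted covariance block
                V = fit.cov.loc[cols, cols].to_numpy()
                chi2 = float(b @ np.linalg.solve(V, b))
                df = len(cols)
                p = float(stats.chi2.sf(chi2, df))
            pvals[f] = p
        worst = max(pvals, key=lambda f: pvals[f])
        if pvals[worst] < alpha:
            break
        trace.append({"removed": worst, "p": pvals[worst]})
        current = current.drop_factors([worst])
        fit = fit_logistic(current, start_params=fit.params)
    return fit, current, trace


def report_models(
    fits: dict[str, ModelFit], lrts: dict[str, tuple[float, int, float]]
) -> pd.DataFrame:
    """Side-by-side OR (99% CI) report for Models 0/1/2 with fit indices.

    Reference levels print 1.00; factors eliminated from a model leave its
    cells blank.
    """
    order = [m for m in ("m0", "m1", "m2") if m in fits]

    def fmt(orv: float, lo: float, hi: float) -> str:
        return f"{orv:.2f} ({lo:.2f}-{hi:.2f})"

    # collect all terms in a stable order: group levels first, then the rest
    terms: list[tuple[str, str]] = []  # (factor, term/level)
    seen = set()
    for m in order:
        for factor, cols in fits[m].factors.items():
            ref = REFERENCE_LEVELS.get(factor)
            if factor not in seen:
                seen.add(factor)
                if ref is not None and cols and "[" in cols[0]:
                    terms.append((factor, f"{factor}[{ref}] (ref)"))
                for c in cols:
                    terms.append((factor, c))
            else:
                for c in cols:
                    if (factor, c) not in terms:
                        terms.append((factor, c))

    rows = []
    for factor, term in terms:
        row = {"factor": factor, "term": term}
        for m in order:
            fitm = fits[m]
            if factor not in fitm.factors:
                row[m] = ""
            elif term.endswith("(ref)"):
                row[m] = "1.00"
            else:
                tab = fitm.or_table.set_index("term")
                if term in tab.index:
                    row[m] = fmt(
                        tab.at[term, "OR"], tab.at[term, "ci_low"], tab.at[term, "ci_high"]
                    )
                else:
                    row[m] = ""
        rows.append(row)
    for name, getter in (
        ("McFadden R2", lambda f: f"{f.mcfadden_r2:.4f}"),
        ("Residual deviance", lambda f: f"{f.deviance:.1f}"),
        ("Residual df", lambda f: str(f.df_residual)),
    ):
        rows.append(
            {"factor": "fit", "term": name, **{m: getter(fits[m]) for m in order}}
        )
    lrt_row = {"factor": "fit", "term": "LRT p (vs previous)"}
    for m in order:
        if m in lrts:
            p = lrts[m][2]
            lrt_row[m] = "< 0.001" if p < 0.001 else f"{p:.3f}"
        else:
            lrt_row[m] = "-"
    rows.append(lrt_row)
    return pd.DataFrame(rows, columns=["factor", "term"] + order)
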