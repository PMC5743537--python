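"""Within-season selection for breeding time and its between-year trends.

For each year and demographic rate a GLM of the rate on *relative lay date*
(days since the year's earliest lay date) gives a slope — the within-season
selection for breeding time, negative when early breeders do better — and an
intercept — the fitted performance of the earliest breeder.  Annual slopes
are then regressed on year (temporal trend) or on the annual degree of
phenological matching, weighting each year by 1/SE of its slope to reflect
sample-size-related uncertainty.

Yearly fits use first nest attempts and keep nests that failed after
hatching (failure can itself reflect food shortage) while excluding nests
that failed before hatching (predominantly predation).

GLM families are the canonical choices per response type: binomial/logit for
nest success and adult survival, Poisson/log for fledgling and recruit
counts, Gaussian/identity for nestling weight (record-level, with nestling
age and brood size among the covariates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from wheatear_phenology.matching import CorrelationResult
from scipy import stats

__all__ = [
    "RATES",
    "FAMILIES",
    "SelectionEstimate",
    "TrendFit",
    "relative_lay_date",
    "fit_yearly_selection",
    "fit_all_years",
    "weighted_trend",
    "slope_intercept_correlation",
    "linearity_check",
]

RATES = ("nest_success", "nestling_weight", "fledglings", "recruits", "male_survival", "female_survival")

FAMILIES: dict[str, str] = {
    "nest_success": "binomial",
    "nestling_weight": "gaussian",
    "fledglings": "poisson",
    "recruits": "poisson",
    "male_survival": "binomial",
    "female_survival": "binomial",
}

RESPONSE_COLUMN = {
    "nest_success": "nest_success",
    "fledglings": "n_fledglings",
    "recruits": "n_recruits",
    "male_survival": "male_survival",
    "female_survival": "female_survival",
}

MIN_RECORDS_PER_YEAR = 5


@dataclass
class SelectionEstimate:
    """Per-year within-season slope for one demographic rate (link scale)."""

    year: int
    rate: str
    covariate_set: str
    slope: float = np.nan
    slope_se: float = np.nan
    intercept: float = np.nan
    n: int = 0
    flag: str = ""

    @property
    def ok(self) -> bool:
        return self.flag == "" and np.isfinite(self.slope_se) and self.slope_se > 0


@dataclass
class TrendFit:
    """Weighted regression of annual slopes (or rates) on a predictor."""

    response: str
    predictor: str
    estimate: float
    se: float
    t: float
    p: float
    r2: float
    n_years: int
    weights: np.ndarray = field(repr=False, default=None)

    @property
    def df(self) -> int:
        return self.n_years - 2


def relative_lay_date(records: pd.DataFrame) -> pd.Series:
    """Lay date minus the year's earliest lay date, in days (earliest → 0)."""
    if len(records) == 0:
        raise ValueError("no records")
    ordinals = records["lay_date"].map(lambda d: pd.Timestamp(d).toordinal())
    return (ordinals - ordinals.groupby(records["year"]).transform("min")).astype(float).rename("rel_lay")


def _fitness_subset(records: pd.DataFrame) -> pd.DataFrame:
    """First attempts, excluding nests that failed before hatching."""
    keep = (records["first_attempt"] == 1) & (records["failed_before_hatching"] == 0)
    return records[keep]


def _build_design(
    grp: pd.DataFrame,
    rate: str,
    covariate_set: str,
    nestling_weights: pd.DataFrame | None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Response vector and design matrix (constant first, rel_lay second)."""
    grp = grp.copy()
    grp["rel_lay"] = grp["lay_date"].map(lambda d: pd.Timestamp(d).toordinal())
    grp["rel_lay"] -= grp["rel_lay"].min()
    age_col = "male_age" if rate == "male_survival" else "female_age"

    if rate == "nestling_weight":
        if nestling_weights is None:
            raise ValueError("nestling_weight fits need the nestling-weight table")
        merged = nestling_weights.merge(
            grp[["nest_id", "rel_lay", "field_layer", age_col, "rain_days", "n_fledglings"]],
            on="nest_id",
            how="inner",
        )
        y = merged["weight"].to_numpy(dtype=float)
        cols = [merged["rel_lay"].to_numpy(dtype=float)]
        if covariate_set == "standard":
            cols += [
                merged["nestling_age"].to_numpy(dtype=float),
                merged["n_fledglings"].to_numpy(dtype=float),  # brood size at weighing
                (merged["field_layer"] == "tall").to_numpy(dtype=float),
                (merged[age_col] == "young").to_numpy(dtype=float),
                merged["rain_days"].to_numpy(dtype=float),
            ]
        n_units = merged["nest_id"].nunique()
    else:
        y = grp[RESPONSE_COLUMN[rate]].to_numpy(dtype=float)
        cols = [grp["rel_lay"].to_numpy(dtype=float)]
        if covariate_set == "standard":
            cols += [
                (grp["field_layer"] == "tall").to_numpy(dtype=float),
                (grp[age_col] == "young").to_numpy(dtype=float),
                grp["rain_days"].to_numpy(dtype=float),
            ]
        n_units = len(grp)
    X = sm.add_constant(np.column_stack(cols), has_constant="add")
    return y, X, n_units


def _glm_family(name: str):
    return {
        "binomial": sm.families.Binomial(),
        "poisson": sm.families.Poisson(),
        "gaussian": sm.families.Gaussian(),
    }[name]


def fit_yearly_selection(
    records: pd.DataFrame,
    year: int,
    rate: str,
    covariate_set: str = "none",
    nestling_weights: pd.DataFrame | None = None,
) -> SelectionEstimate:
    """GLM of one rate on relative lay date within one year.

    Returns a flagged (excluded) estimate rather than raising when the year
    is degenerate: too few records, constant response or lay dates, GLM
    non-convergence, or separation (binary response all 0 or all 1).
    """
    est = SelectionEstimate(year=int(year), rate=rate, covariate_set=covariate_set)
    grp = _fitness_subset(records)
    grp = grp[grp["year"] == year]
    if len(grp) < MIN_RECORDS_PER_YEAR:
        est.flag = f"n<{MIN_RECORDS_PER_YEAR}"
        return est
    y, X, n_units = _build_design(grp, rate, covariate_set, nestling_weights)
    est.n = n_units
    if len(y) < MIN_RECORDS_PER_YEAR:
        est.flag = f"n<{MIN_RECORDS_PER_YEAR}"
        return est
    if np.ptp(X[:, 1]) == 0:
        est.flag = "constant lay date"
        return est
    family_name = FAMILIES[rate]
    if family_name == "binomial" and len(np.unique(y)) < 2:
        est.flag = "separation: constant binary response"
        return est
    if family_name == "poisson" and y.sum() == 0:
        est.flag = "all-zero counts"
        return est
    if family_name == "gaussian" and np.ptp(y) == 0:
        # constant response: slope is exactly 0 but its SE is degenerate
        est.slope, est.intercept, est.slope_se = 0.0, float(y[0]), np.nan
        est.flag = "constant response"
        return est
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            fit = sm.GLM(y, X, family=_glm_family(family_name)).fit()
    except Exception as exc:  # noqa: BLE001 - any numerical failure flags the year
        est.flag = f"fit failed: {type(exc).__name__}"
        return est
    if not fit.converged:
        est.flag = "non-convergence"
        return est
    est.intercept = float(fit.params[0])
    est.slope = float(fit.params[1])
    est.slope_se = float(fit.bse[1])
    if not np.isfinite(est.slope_se) or est.slope_se > 1e3:
        est.flag = "separation: unbounded slope SE"
    return est


def fit_all_years(
    records: pd.DataFrame,
    rate: str,
    covariate_set: str = "none",
    nestling_weights: pd.DataFrame | None = None,
) -> list[SelectionEstimate]:
    years = sorted(records["year"].unique())
    return [fit_yearly_selection(records, y, rate, covariate_set, nestling_weights) for y in years]


def weighted_trend(
    estimates: list[SelectionEstimate],
    predictor: str,
    predictor_values: dict[int, float] | None = None,
    weight_rule: str = "inv_se",
) -> TrendFit:
    """Weighted least squares of annual slopes on year or on annual matching.

    Weights are literally 1/SE (``weight_rule="inv_se"``, the default) —
    sample-size-related uncertainty weighting — with 1/SE² available as a
    sensitivity option (``"inv_var"``).

    Parameters
    ----------
    estimates
        Per-year slope estimates; flagged years are dropped.
    predictor
        ``"year"`` or a name for the values in ``predictor_values``
        (e.g. ``"median_ts"``).
    predictor_values
        Mapping year → predictor value; required unless ``predictor="year"``.
    """
    good = [e for e in estimates if e.ok]
    if any(e.flag == "" and not (np.isfinite(e.slope_se) and e.slope_se > 0) for e in estimates):
        raise ValueError("non-positive slope SE in unflagged estimate")
    if len(good) < 3:
        raise ValueError(f"need >=3 usable years for a weighted trend, have {len(good)}")
    if predictor == "year":
        x = np.array([float(e.year) for e in good])
    else:
        if predictor_values is None:
            raise ValueError(f"predictor_values required for predictor {predictor!r}")
        x = np.array([float(predictor_values[e.year]) for e in good])
    ydata = np.array([e.slope for e in good])
    se = np.array([e.slope_se for e in good])
    w = 1.0 / se if weight_rule == "inv_se" else 1.0 / se**2
    fit = sm.WLS(ydata, sm.add_constant(x), weights=w).fit()
    rate = good[0].rate
    return TrendFit(
        response=f"slope[{rate}]",
        predictor=predictor,
        estimate=float(fit.params[1]),
        se=float(fit.bse[1]),
        t=float(fit.tvalues[1]),
        p=float(fit.pvalues[1]),
        r2=float(fit.rsquared),
        n_years=len(good),
        weights=w,
    )


def annual_rate_means(records: pd.DataFrame, rate: str, nestling_weights: pd.DataFrame | None = None) -> pd.Series:
    """Yearly mean of a demographic rate on the fitness subset (for reports)."""
    grp = _fitness_subset(records)
    if rate == "nestling_weight":
        if nestling_weights is None:
            raise ValueError("nestling_weight means need the nestling-weight table")
        merged = nestling_weights.merge(grp[["nest_id", "year"]], on="nest_id", how="inner")
        return merged.groupby("year")["weight"].mean()
    return grp.groupby("year")[RESPONSE_COLUMN[rate]].mean()


def slope_intercept_correlation(estimates: list[SelectionEstimate]) -> CorrelationResult:
    """Pearson correlation of yearly intercepts and slopes (no-covariate fits).

    A strongly negative correlation indicates that flattening seasonal
    declines are driven by deteriorating early-breeder performance.
    """
    good = [e for e in estimates if e.ok]
    if len(good) < 3:
        raise ValueError("need >=3 usable years")
    slopes = np.array([e.slope for e in good])
    intercepts = np.array([e.intercept for e in good])
    if np.ptp(slopes) == 0 or np.ptp(intercepts) == 0:
        raise ValueError("undefined correlation: zero variance")
    r, p = stats.pearsonr(intercepts, slopes)
    df = len(good) - 2
    t = r * np.sqrt(df / (1 - r**2)) if abs(r) < 1 else np.inf * np.sign(r)
    return CorrelationResult(r=float(r), t=float(t), df=df, p=float(p))


@dataclass
class LinearityCheck:
    year: int
    rate: str
    aic_linear: float = np.nan
    aic_quadratic: float = np.nan
    preferred: str = ""
    flag: str = ""


def linearity_check(
    records: pd.DataFrame,
    year: int,
    rate: str,
    nestling_weights: pd.DataFrame | None = None,
    min_n: int = 8,
) -> LinearityCheck:
    """AIC comparison of linear vs quadratic lay-date effects (informational).

    The pipeline always uses linear slopes; this check documents whether the
    data would have preferred curvature.
    """
    out = LinearityCheck(year=int(year), rate=rate)
    grp = _fitness_subset(records)
    grp = grp[grp["year"] == year]
    if len(grp) < min_n:
        out.flag = f"n<{min_n}: comparison skipped"
        return out
    y, X, _ = _build_design(grp, rate, "none", nestling_weights)
    if np.ptp(X[:, 1]) == 0:
        out.flag = "constant lay date"
        return out
    fam = _glm_family(FAMILIES[rate])
    Xq = np.column_stack([X, X[:, 1] ** 2])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            lin = sm.GLM(y, X, family=fam).fit()
            quad = sm.GLM(y, Xq, family=fam).fit()
    except Exception as exc:  # noqa: BLE001
        out.flag = f"fit failed: {type(exc).__name__}"
        return out
    out.aic_linear = float(lin.aic)
    out.aic_quadratic = float(quad.aic)
    out.preferred = "linear" if lin.aic <= quad.aic else "quadratic"
    return out
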