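"""Grid search for the thermal indicator of spring progression.

Different arthropod taxa develop above different base temperatures, so the
"right" thermal clock for a breeding-phenology analysis is unknown a priori.
The procedure here scans a grid of candidate (base temperature, thermal-sum
threshold) pairs, computes each candidate's annual threshold-crossing date,
regresses annual median lay date (day-of-year) on those crossing dates, and
keeps the candidate with the largest R².

Thresholds run in fixed steps (default 100 degree-days) up to a per-base
ceiling: the minimum over years of the thermal sum accumulated by that
year's latest first-clutch lay date.  The ceiling guarantees every retained
candidate has a crossing date in every year.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from wheatear_phenology.thermal import (
    ClimateSeries,
    DegreeDayParams,
    date_of_threshold,
    thermal_sum_at,
    thermal_sum_series,
)

__all__ = [
    "CandidateIndicator",
    "SpringIndicator",
    "candidate_grid",
    "evaluate_candidate",
    "select_best",
    "derive_spring_indicator",
]

DEFAULT_T_BASE_GRID = tuple(range(-5, 11))  # °C, inclusive
DEFAULT_THRESHOLD_STEP = 100.0  # degree-days
MIN_YEARS = 3


class SelectionError(RuntimeError):
    """No valid candidate indicator could be selected."""


@dataclass
class CandidateIndicator:
    """One (t_base, threshold) candidate with its lay-date regression."""

    t_base: float
    threshold: float
    dates: dict[int, dt.date | None]
    slope: float = np.nan
    intercept: float = np.nan
    slope_se: float = np.nan
    r2: float = np.nan
    n_years: int = 0
    valid: bool = False
    reason: str = ""

    def date_doy(self, year: int) -> float:
        d = self.dates.get(year)
        return float(d.timetuple().tm_yday) if d is not None else np.nan


@dataclass
class SpringIndicator:
    """Winning candidate plus the full provenance grid."""

    best: CandidateIndicator
    grid: pd.DataFrame = field(repr=False)
    ties: list[tuple[float, float]] = field(default_factory=list)

    @property
    def t_base(self) -> float:
        return self.best.t_base

    @property
    def threshold(self) -> float:
        return self.best.threshold

    def spring_date(self, year: int) -> dt.date | None:
        return self.best.dates.get(year)


def candidate_grid(
    series: ClimateSeries,
    latest_lay: dict[int, dt.date],
    t_base_grid: tuple[float, ...] = DEFAULT_T_BASE_GRID,
    threshold_step: float = DEFAULT_THRESHOLD_STEP,
) -> list[tuple[float, float]]:
    """Cartesian candidate grid with per-base threshold ceilings.

    Parameters
    ----------
    series
        Daily climate series covering the study years.
    latest_lay
        Per-year latest first-clutch lay date; defines the end of the
        egg-laying period used for the threshold ceiling.
    t_base_grid
        Base temperatures (°C) to scan.
    threshold_step
        Threshold spacing (degree-days); thresholds are multiples of this.

    Returns
    -------
    list of (t_base, threshold)
        Empty per-base candidate sets (ceiling below one step) are simply
        absent from the result.
    """
    if len(t_base_grid) == 0 or threshold_step <= 0 or not latest_lay:
        raise ValueError("empty candidate grid configuration")
    pairs: list[tuple[float, float]] = []
    for t_base in t_base_grid:
        params = DegreeDayParams(float(t_base))
        ceilings = []
        for year, lay in latest_lay.items():
            ts = thermal_sum_series(series, params, year)
            ceilings.append(thermal_sum_at(ts, lay))
        ceiling = min(ceilings)
        n_steps = int(np.floor(ceiling / threshold_step))
        pairs.extend((float(t_base), threshold_step * k) for k in range(1, n_steps + 1))
    if not pairs:
        raise ValueError("candidate grid is empty: every threshold ceiling is below one step")
    return pairs


def evaluate_candidate(
    series: ClimateSeries,
    annual_median_lay: dict[int, dt.date],
    t_base: float,
    threshold: float,
) -> CandidateIndicator:
    """OLS of annual median lay date on the candidate's crossing dates.

    Both variables enter as day-of-year.  Candidates missing a crossing date
    in any year with a median lay date, with fewer than three usable years,
    or with zero predictor variance are flagged invalid and excluded from
    selection.
    """
    params = DegreeDayParams(float(t_base))
    dates: dict[int, dt.date | None] = {}
    for year in sorted(annual_median_lay):
        ts = thermal_sum_series(series, params, year)
        dates[year] = date_of_threshold(ts, threshold)
    cand = CandidateIndicator(t_base=float(t_base), threshold=float(threshold), dates=dates)

    years = sorted(annual_median_lay)
    x = np.array([cand.date_doy(y) for y in years])
    y = np.array([float(annual_median_lay[yr].timetuple().tm_yday) for yr in years])
    if np.isnan(x).any():
        cand.reason = "threshold not reached in all years"
        return cand
    if len(years) < MIN_YEARS:
        cand.reason = f"fewer than {MIN_YEARS} years"
        return cand
    if np.ptp(x) == 0:
        cand.reason = "zero-variance predictor"
        return cand
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    cand.intercept, cand.slope = fit.params
    cand.slope_se = float(fit.bse[1])
    cand.r2 = float(fit.rsquared)
    cand.n_years = len(years)
    cand.valid = True
    return cand


def select_best(candidates: list[CandidateIndicator]) -> SpringIndicator:
    """Pick the candidate with maximal R².

    Ties on R² (to 12 decimals) are broken deterministically: higher base
    temperature first, then lower threshold; tied pairs are recorded in
    ``ties`` for the provenance report.
    """
    valid = [c for c in candidates if c.valid]
    if not valid:
        raise SelectionError("no valid candidate indicator (all flagged)")
    best = max(valid, key=lambda c: (round(c.r2, 12), c.t_base, -c.threshold))
    ties = [
        (c.t_base, c.threshold)
        for c in valid
        if round(c.r2, 12) == round(best.r2, 12) and (c.t_base, c.threshold) != (best.t_base, best.threshold)
    ]
    grid = pd.DataFrame(
        {
            "t_base": [c.t_base for c in candidates],
            "threshold": [c.threshold for c in candidates],
            "n_years": [c.n_years for c in candidates],
            "slope": [c.slope for c in candidates],
            "slope_se": [c.slope_se for c in candidates],
            "r2": [c.r2 for c in candidates],
            "valid": [c.valid for c in candidates],
            "reason": [c.reason for c in candidates],
        }
    )
    grid["winner"] = (grid["t_base"] == best.t_base) & (grid["threshold"] == best.threshold)
    return SpringIndicator(best=best, grid=grid, ties=ties)


def derive_spring_indicator(
    series: ClimateSeries,
    annual_median_lay: dict[int, dt.date],
    latest_lay: dict[int, dt.date],
    t_base_grid: tuple[float, ...] = DEFAULT_T_BASE_GRID,
    threshold_step: float = DEFAULT_THRESHOLD_STEP,
) -> SpringIndicator:
    """Full grid search: build candidates, evaluate each, select the best."""
    pairs = candidate_grid(series, latest_lay, t_base_grid, threshold_step)
    candidates = [evaluate_candidate(series, annual_median_lay, tb, th) for tb, th in pairs]
    return select_best(candidates)
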