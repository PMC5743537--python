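"""Phenological matching between breeding time and thermal spring.

Two annual measures of matching are computed and cross-validated:

* **day difference** — annual median lay date minus the spring-progression
  date (the indicator's threshold-crossing date).  Positive values mean the
  population bred later than thermal spring.
* **thermal sum at breeding** — the cumulative thermal sum on each nest's
  lay (or hatch) date, summarized per year by its median.  Higher values
  likewise mean later breeding in thermal terms.

On any data where within-year thermal-sum curves increase through the laying
period the two measures are monotonically related; their Pearson correlation
is reported with its t statistic on n−2 degrees of freedom.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from wheatear_phenology.spring import SpringIndicator
from wheatear_phenology.thermal import ClimateSeries, DegreeDayParams, thermal_sum_at, thermal_sum_series

__all__ = [
    "BREEDING_COLUMNS",
    "CorrelationResult",
    "derive_hatch_date",
    "lower_median",
    "individual_thermal_sum",
    "annual_matching",
    "correlate_matching_measures",
]

#: canonical breeding-record table schema (one row = one nest attempt)
BREEDING_COLUMNS = [
    "nest_id",
    "year",
    "territory",
    "female",
    "male",
    "lay_date",
    "clutch_size",
    "hatch_date",
    "field_layer",  # {"short", "tall"}
    "female_age",  # {"young", "old"}
    "male_age",
    "nest_success",  # 0/1
    "n_fledglings",
    "n_recruits",
    "female_survival",  # returned next year, 0/1
    "male_survival",
    "rain_days",  # days with rain >0 mm in the 16-day nestling period
    "first_attempt",  # 0/1
    "failed_before_hatching",  # 0/1
]

DEFAULT_INCUBATION_DAYS = 13
DEFAULT_EGGS_PER_DAY = 1
NESTLING_PERIOD_DAYS = 16


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its t test."""

    r: float
    t: float
    df: int
    p: float


def derive_hatch_date(
    lay_date: dt.date,
    clutch_size: int,
    incubation_days: int = DEFAULT_INCUBATION_DAYS,
    eggs_per_day: int = DEFAULT_EGGS_PER_DAY,
) -> dt.date:
    """Hatch date from lay date under a standard passerine schedule.

    One egg per day is laid and incubation (default 13 days) starts with the
    last egg, so ``hatch = lay + (clutch - 1) / eggs_per_day + incubation``.
    """
    laying_span = int(np.ceil((clutch_size - 1) / eggs_per_day))
    return lay_date + dt.timedelta(days=laying_span + incubation_days)


def lower_median(values: pd.Series | np.ndarray) -> float:
    """Lower median: order statistic at ceil(n/2); keeps medians on observed values."""
    arr = np.sort(np.asarray(values))
    if len(arr) == 0:
        raise ValueError("median of empty set")
    return arr[(len(arr) - 1) // 2]


def lower_median_date(dates: pd.Series) -> dt.date:
    ordinals = np.array([d.toordinal() for d in dates])
    return dt.date.fromordinal(int(lower_median(ordinals)))


def individual_thermal_sum(
    records: pd.DataFrame,
    series: ClimateSeries,
    t_base: float = 3.0,
    at: str = "lay",
) -> pd.Series:
    """Thermal sum on each record's lay or hatch date.

    Parameters
    ----------
    records
        Breeding-record table with ``year`` and ``lay_date``/``hatch_date``.
    series
        Climate series covering the record years.
    t_base
        Base temperature (°C); default 3 °C, the winning indicator's base on
        the original study data.
    at
        ``"lay"`` or ``"hatch"``.  Missing hatch dates are derived from lay
        date and clutch size via :func:`derive_hatch_date`.

    Returns
    -------
    pandas.Series
        Degree-day sums aligned with ``records.index``.
    """
    if at not in ("lay", "hatch"):
        raise ValueError(f"at must be 'lay' or 'hatch', got {at!r}")
    params = DegreeDayParams(float(t_base))
    ts_by_year = {int(y): thermal_sum_series(series, params, int(y)) for y in records["year"].unique()}
    out = np.empty(len(records))
    for i, (_, row) in enumerate(records.iterrows()):
        if at == "lay":
            date = row["lay_date"]
        else:
            date = row.get("hatch_date")
            if date is None or (isinstance(date, float) and np.isnan(date)) or pd.isna(date):
                if pd.isna(row.get("clutch_size")):
                    raise ValueError(f"record {row.get('nest_id', i)}: no hatch date and no clutch size to derive it")
                date = derive_hatch_date(_as_date(row["lay_date"]), int(row["clutch_size"]))
        ts = ts_by_year[int(row["year"])]
        out[i] = thermal_sum_at(ts, _as_date(date))
    return pd.Series(out, index=records.index, name=f"ts_{at}")


def _as_date(d) -> dt.date:
    if isinstance(d, pd.Timestamp):
        return d.date()
    if isinstance(d, dt.datetime):
        return d.date()
    return d


def annual_matching(
    records: pd.DataFrame,
    series: ClimateSeries,
    indicator: SpringIndicator,
    t_base: float | None = None,
) -> pd.DataFrame:
    """Annual summary table of breeding phenology and matching measures.

    Uses first nest attempts only.  Returns one row per year with the
    (lower) median lay date, the spring-progression date, their day
    difference (positive = breeding later than thermal spring), the medians
    of individual thermal sums at lay and hatch, and the number of pairs.
    Years present in the indicator but without records are omitted with a
    warning.
    """
    t_base = indicator.t_base if t_base is None else t_base
    firsts = records[records["first_attempt"] == 1]
    rows = []
    for year in sorted(y for y in indicator.best.dates):
        grp = firsts[firsts["year"] == year]
        if len(grp) == 0:
            warnings.warn(f"year {year}: no breeding records, omitted from annual summary")
            continue
        spring = indicator.spring_date(year)
        if spring is None:
            warnings.warn(f"year {year}: indicator has no crossing date, omitted")
            continue
        median_lay = lower_median_date(grp["lay_date"].map(_as_date))
        ts_lay = individual_thermal_sum(grp, series, t_base, at="lay")
        ts_hatch = individual_thermal_sum(grp, series, t_base, at="hatch")
        rows.append(
            {
                "year": year,
                "median_lay_date": median_lay,
                "median_lay_doy": median_lay.timetuple().tm_yday,
                "spring_date": spring,
                "spring_doy": spring.timetuple().tm_yday,
                "match_daydiff": (median_lay - spring).days,
                "match_median_ts_lay": lower_median(ts_lay),
                "match_median_ts_hatch": lower_median(ts_hatch),
                "n_pairs": len(grp),
            }
        )
    return pd.DataFrame(rows)


def correlate_matching_measures(summaries: pd.DataFrame, ts_column: str = "match_median_ts_lay") -> CorrelationResult:
    """Pearson correlation between the thermal-sum and day-difference measures."""
    x = summaries[ts_column].to_numpy(dtype=float)
    y = summaries["match_daydiff"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 years to correlate matching measures")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: a matching measure has zero variance")
    r, p = stats.pearsonr(x, y)
    df = len(x) - 2
    t = r * np.sqrt(df / (1 - r**2)) if abs(r) < 1 else np.inf * np.sign(r)
    return CorrelationResult(r=float(r), t=float(t), df=df, p=float(p))
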