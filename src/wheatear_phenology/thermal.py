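"""Degree days and accumulated thermal sums from a daily climate series.

Arthropod (and plant) development rates are approximately linear in
temperature above a taxon-specific base temperature, so the progression of
spring can be indexed by the accumulated sum of positive degree days

    DD(day) = max(Tmean(day) - Tbase, 0)
    TS(day) = sum of DD from January 1 through ``day``

for a given base temperature ``Tbase``.  The date on which TS first reaches a
critical threshold is a candidate indicator of how far thermal spring has
progressed in that year.

Truncation at zero happens per day, before accumulation: a cold day
contributes nothing, it does not cancel previously accrued warmth.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClimateSeries",
    "DegreeDayParams",
    "ThermalSumSeries",
    "degree_day",
    "thermal_sum_series",
    "date_of_threshold",
    "thermal_sum_at",
]

#: longest run of missing days that may be filled by linear interpolation
MAX_INTERPOLATION_GAP = 3


class MissingDataError(ValueError):
    """A requested year or date is not covered by the climate series."""


@dataclass(frozen=True)
class DegreeDayParams:
    """Parameters of the degree-day computation.

    Parameters
    ----------
    t_base
        Base temperature in °C below which a day accrues no degree days.
    """

    t_base: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.t_base):
            raise ValueError("t_base must be finite")


def degree_day(tmean: float, t_base: float) -> float:
    """Positive degree days accrued by one day.

    ``DD = Tmean - Tbase`` truncated at zero; a day at or below the base
    temperature contributes nothing.

    Parameters
    ----------
    tmean
        Daily mean temperature (°C).
    t_base
        Base temperature (°C).

    Returns
    -------
    float
        ``max(tmean - t_base, 0.0)``.
    """
    if not (np.isfinite(tmean) and np.isfinite(t_base)):
        raise ValueError(f"degree_day requires finite inputs, got ({tmean!r}, {t_base!r})")
    return max(float(tmean) - float(t_base), 0.0)


class ClimateSeries:
    """Daily mean temperature and precipitation for one location.

    Wraps a DataFrame with columns ``date`` (datetime64), ``tmean_c`` and
    ``precip_mm``, covering whole calendar years at daily resolution.
    Gaps of up to :data:`MAX_INTERPOLATION_GAP` consecutive missing days are
    filled by linear interpolation of temperature (precipitation is filled
    with zero); longer gaps raise :class:`MissingDataError`.
    """

    def __init__(self, frame: pd.DataFrame, interpolate: bool = True):
        required = {"date", "tmean_c", "precip_mm"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"climate frame missing columns: {sorted(missing)}")
        df = frame.loc[:, ["date", "tmean_c", "precip_mm"]].copy()
        df["date"] = pd.to_datetime(df["date"])
        if df["date"].duplicated().any():
            dups = df.loc[df["date"].duplicated(), "date"].dt.date.tolist()
            raise ValueError(f"duplicate climate dates: {dups[:5]}")
        df = df.sort_values("date").reset_index(drop=True)
        if len(df) == 0:
            raise ValueError("empty climate series")
        if interpolate:
            df = self._reindex_and_interpolate(df)
        self._validate(df)
        self._frame = df
        self._by_year = {int(y): g.reset_index(drop=True) for y, g in df.groupby(df["date"].dt.year)}
        self._first_ordinal = df["date"].iloc[0].toordinal()
        self._precip = df["precip_mm"].to_numpy(dtype=float)

    @staticmethod
    def _reindex_and_interpolate(df: pd.DataFrame) -> pd.DataFrame:
        first = df["date"].iloc[0]
        last = df["date"].iloc[-1]
        start = pd.Timestamp(year=first.year, month=1, day=1)
        end = pd.Timestamp(year=last.year, month=12, day=31)
        full = pd.DataFrame({"date": pd.date_range(start, end, freq="D")})
        merged = full.merge(df, on="date", how="left")
        gap = merged["tmean_c"].isna()
        if gap.any():
            run = gap.groupby((~gap).cumsum()).transform("sum")
            too_long = gap & (run > MAX_INTERPOLATION_GAP)
            if too_long.any():
                bad = merged.loc[too_long, "date"].dt.date
                raise MissingDataError(
                    f"climate gap longer than {MAX_INTERPOLATION_GAP} days "
                    f"starting {bad.iloc[0]} ({int(too_long.sum())} days total)"
                )
            merged["tmean_c"] = merged["tmean_c"].interpolate(method="linear", limit_area="inside")
            if merged["tmean_c"].isna().any():
                bad = merged.loc[merged["tmean_c"].isna(), "date"].dt.date
                raise MissingDataError(f"cannot interpolate at series edge, e.g. {bad.iloc[0]}")
            merged["precip_mm"] = merged["precip_mm"].fillna(0.0)
        return merged

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if not np.isfinite(df["tmean_c"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite temperatures in climate series")
        if (df["precip_mm"].to_numpy(dtype=float) < 0).any():
            raise ValueError("negative precipitation in climate series")
        step = df["date"].diff().dropna()
        if not (step == pd.Timedelta(days=1)).all():
            raise ValueError("climate series must be daily with no gaps after interpolation")

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def years(self) -> list[int]:
        return sorted(self._by_year)

    def year_frame(self, year: int) -> pd.DataFrame:
        """Rows of one calendar year, Jan 1 through Dec 31."""
        try:
            g = self._by_year[int(year)]
        except KeyError:
            raise MissingDataError(f"year {year} not in climate series ({self.years[0]}–{self.years[-1]})")
        first = g["date"].iloc[0]
        n_expected = 366 if first.is_leap_year else 365
        if first.dayofyear != 1 or len(g) != n_expected:
            raise MissingDataError(f"year {year} incomplete in climate series ({len(g)} days)")
        return g

    def rain_days(self, start: dt.date, n_days: int) -> int:
        """Number of days with precipitation > 0 mm in ``[start, start + n_days)``."""
        i0 = pd.Timestamp(start).toordinal() - self._first_ordinal
        if i0 < 0 or i0 + n_days > len(self._precip):
            raise MissingDataError(f"rain window {start} (+{n_days}d) not fully covered")
        return int((self._precip[i0 : i0 + n_days] > 0).sum())


@dataclass
class ThermalSumSeries:
    """Per-day cumulative thermal sum for one calendar year and base temperature."""

    year: int
    t_base: float
    values: np.ndarray = field(repr=False)  # cumulative TS, one entry per day from Jan 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.values) < 0):
            raise ValueError("thermal sums must be non-decreasing")

    def __len__(self) -> int:
        return len(self.values)

    def _doy_index(self, date: dt.date) -> int:
        if date.year != self.year:
            raise ValueError(f"date {date} outside series year {self.year}")
        return date.timetuple().tm_yday - 1

    def date_for_index(self, idx: int) -> dt.date:
        return dt.date(self.year, 1, 1) + dt.timedelta(days=int(idx))


def thermal_sum_series(series: ClimateSeries, params: DegreeDayParams, year: int) -> ThermalSumSeries:
    """Cumulative thermal sum from Jan 1 for one year.

    Daily degree days are truncated at zero individually, then accumulated in
    date order; Feb 29 is an ordinary accumulation day.
    """
    g = series.year_frame(year)
    dd = np.maximum(g["tmean_c"].to_numpy(dtype=float) - params.t_base, 0.0)
    return ThermalSumSeries(year=int(year), t_base=params.t_base, values=np.cumsum(dd))


def date_of_threshold(ts: ThermalSumSeries, threshold: float) -> dt.date | None:
    """First date whose cumulative thermal sum reaches ``threshold``.

    Returns ``None`` when the threshold is never reached in the year; that is
    a valid outcome (candidate indicators which miss years are excluded
    upstream rather than imputed).
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    idx = np.searchsorted(ts.values, threshold, side="left")
    if idx >= len(ts.values):
        return None
    return ts.date_for_index(int(idx))


def thermal_sum_at(ts: ThermalSumSeries, date: dt.date) -> float:
    """Cumulative thermal sum on a given calendar date of the series year."""
    return float(ts.values[ts._doy_index(date)])
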