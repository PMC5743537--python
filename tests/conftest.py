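"""Shared fixtures: tiny hand-checkable series and study-scale synthetic data."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from wheatear_phenology import simulate as sim
from wheatear_phenology.thermal import ClimateSeries


def make_climate(tmeans, year=2000, precip=None) -> ClimateSeries:
    """Climate series for one year whose first ``len(tmeans)`` days are given.

    Remaining days are filled with a constant −10 °C so they accrue nothing
    at the base temperatures under test.
    """
    n_year = 366 if dt.date(year, 12, 31).timetuple().tm_yday == 366 else 365
    t = np.full(n_year, -10.0)
    t[: len(tmeans)] = tmeans
    p = np.zeros(n_year)
    if precip is not None:
        p[: len(precip)] = precip
    dates = pd.date_range(f"{year}-01-01", periods=n_year, freq="D")
    return ClimateSeries(pd.DataFrame({"date": dates, "tmean_c": t, "precip_mm": p}))


@pytest.fixture(scope="session")
def toy_climate() -> ClimateSeries:
    """The worked 5-day example: tmeans [4, 2, 6, 3, 1], base 3 → TS [1, 1, 4, 4, 4]."""
    return make_climate([4.0, 2.0, 6.0, 3.0, 1.0])


@pytest.fixture(scope="session")
def study_climate() -> ClimateSeries:
    """20-year warming climate at the default study conditions."""
    return sim.generate_climate(sim.ClimateGenConfig(), seed=7)


@pytest.fixture(scope="session")
def baseline_data(study_climate):
    """Study-scale baseline breeding dataset (records, nestling weights)."""
    cfg = sim.scenario_presets("baseline")
    records, weights = sim.generate_population(study_climate, cfg, seed=11)
    return records, weights


@pytest.fixture(scope="session")
def small_climate() -> ClimateSeries:
    """Shorter (8-year) climate for cheaper end-to-end runs."""
    return sim.generate_climate(sim.ClimateGenConfig(first_year=1993, last_year=2000), seed=5)


@pytest.fixture(scope="session")
def small_data(small_climate):
    cfg = sim.scenario_presets("baseline")
    records, weights = sim.generate_population(small_climate, cfg, seed=6)
    return records, weights
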