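"""Yearly selection slopes, weighted trend regressions, slope–intercept links."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from wheatear_phenology import selection
from wheatear_phenology.selection import SelectionEstimate


def year_records(
    rel_days,
    responses,
    rate_col,
    year=2000,
    field_layer="short",
    rain=3,
):
    n = len(rel_days)
    base = dt.date(year, 5, 1)
    df = pd.DataFrame(
        {
            "nest_id": [f"N{i}" for i in range(n)],
            "year": year,
            "territory": [f"T{i}" for i in range(n)],
            "female": [f"F{i}" for i in range(n)],
            "male": [f"M{i}" for i in range(n)],
            "lay_date": [base + dt.timedelta(days=int(d)) for d in rel_days],
            "clutch_size": 6,
            "hatch_date": [base + dt.timedelta(days=int(d) + 18) for d in rel_days],
            "field_layer": field_layer,
            "female_age": "old",
            "male_age": "old",
            "nest_success": 1,
            "n_fledglings": 3,
            "n_recruits": 1,
            "female_survival": 1,
            "male_survival": 1,
            "rain_days": rain,
            "first_attempt": 1,
            "failed_before_hatching": 0,
        }
    )
    df[rate_col] = responses
    return df


class TestRelativeLayDate:
    def test_subtraction_examples(self):
        recs = year_records([10, 13, 20], [1, 1, 1], "nest_success")
        rel = selection.relative_lay_date(recs)
        assert list(rel) == [0.0, 3.0, 10.0]

    def test_earliest_maps_to_zero_per_year(self):
        a = year_records([5, 8], [1, 1], "nest_success", year=2000)
        b = year_records([2, 9], [1, 1], "nest_success", year=2001)
        rel = selection.relative_lay_date(pd.concat([a, b], ignore_index=True))
        assert list(rel) == [0.0, 3.0, 0.0, 7.0]

    def test_all_equal_dates_all_zero(self):
        recs = year_records([4, 4, 4], [1, 0, 1], "nest_success")
        assert (selection.relative_lay_date(recs) == 0).all()


class TestFitYearlySelection:
    def test_planted_gaussian_slope_recovered(self):
        rng = np.random.default_rng(1)
        rel = np.repeat(np.arange(0, 20), 3)
        y = 17.0 - 0.12 * rel + rng.normal(0, 0.8, len(rel))
        recs = year_records(rel, 1, "nest_success")
        weights = pd.DataFrame({"nest_id": recs["nest_id"], "nestling_age": 6, "weight": y})
        est = selection.fit_yearly_selection(recs, 2000, "nestling_weight", "none", weights)
        assert est.ok
        assert abs(est.slope - (-0.12)) < 2 * est.slope_se
        # intercept is the fitted earliest-breeder performance
        assert est.intercept == pytest.approx(17.0, abs=0.5)

    def test_planted_poisson_slope_recovered(self):
        rng = np.random.default_rng(2)
        rel = np.tile(np.arange(0, 25), 4)
        lam = np.exp(1.5 - 0.05 * rel)
        recs = year_records(rel, rng.poisson(lam), "n_fledglings")
        est = selection.fit_yearly_selection(recs, 2000, "fledglings")
        assert est.ok
        assert abs(est.slope - (-0.05)) < 2 * est.slope_se

    def test_constant_gaussian_response_gives_zero_slope_flag(self):
        recs = year_records([0, 2, 5, 8, 11, 14], 1, "nest_success")
        weights = pd.DataFrame({"nest_id": recs["nest_id"], "nestling_age": 6, "weight": 15.0})
        est = selection.fit_yearly_selection(recs, 2000, "nestling_weight", "none", weights)
        assert est.slope == 0.0
        assert not est.ok  # degenerate SE: excluded from weighted trends

    def test_all_success_binary_flagged_as_separation(self):
        recs = year_records([0, 2, 5, 8, 11, 14], 1, "nest_success")
        est = selection.fit_yearly_selection(recs, 2000, "nest_success")
        assert not est.ok
        assert "separation" in est.flag

    def test_too_few_records_excluded(self):
        recs = year_records([0, 2, 5], [1, 0, 1], "nest_success")
        est = selection.fit_yearly_selection(recs, 2000, "nest_success")
        assert est.flag.startswith("n<")

    def test_failed_before_hatching_excluded_from_fit(self):
        recs = year_records(np.arange(10), [1, 0] * 5, "nest_success")
        recs.loc[:4, "failed_before_hatching"] = 1
        est = selection.fit_yearly_selection(recs, 2000, "nest_success")
        assert est.n == 5 or est.flag  # only the surviving-by-hatch half enters


def wls_normal_equations(x, y, se):
    """Closed-form weighted normal equations with weights 1/SE (oracle)."""
    w = 1.0 / np.asarray(se)
    X = np.column_stack([np.ones(len(x)), x])
    A = X.T @ np.diag(w) @ X
    b = X.T @ np.diag(w) @ np.asarray(y)
    return np.linalg.solve(A, b)


class TestWeightedTrend:
    def _estimates(self, years, slopes, ses, rate="fledglings"):
        return [
            SelectionEstimate(year=y, rate=rate, covariate_set="none", slope=s, slope_se=se, intercept=0.0, n=30)
            for y, s, se in zip(years, slopes, ses)
        ]

    def test_matches_closed_form_oracle(self):
        years = [1, 2, 3, 4]
        slopes = [-0.10, -0.05, 0.00, 0.02]
        ses = [0.02, 0.02, 0.04, 0.04]
        fit = selection.weighted_trend(self._estimates(years, slopes, ses), "year")
        expected = wls_normal_equations(years, slopes, ses)
        assert fit.estimate == pytest.approx(expected[1], abs=1e-10)

    def test_equal_weights_reduce_to_ols(self):
        years = list(range(1, 9))
        rng = np.random.default_rng(3)
        slopes = rng.normal(-0.05, 0.03, 8)
        fit = selection.weighted_trend(self._estimates(years, slopes, [0.03] * 8), "year")
        ols = sm.OLS(slopes, sm.add_constant(np.array(years, float))).fit()
        assert fit.estimate == pytest.approx(ols.params[1], abs=1e-12)
        assert fit.se == pytest.approx(ols.bse[1], abs=1e-12)

    def test_three_collinear_points_r2_one(self):
        fit = selection.weighted_trend(self._estimates([1, 2, 3], [0.01, 0.02, 0.03], [0.01, 0.02, 0.05]), "year")
        assert fit.r2 == pytest.approx(1.0)

    def test_inverse_variance_option_differs(self):
        years = [1, 2, 3, 4, 5]
        slopes = [-0.1, -0.02, 0.0, 0.05, 0.01]
        ses = [0.01, 0.05, 0.02, 0.08, 0.03]
        ests = self._estimates(years, slopes, ses)
        f1 = selection.weighted_trend(ests, "year", weight_rule="inv_se")
        f2 = selection.weighted_trend(ests, "year", weight_rule="inv_var")
        assert f1.estimate != pytest.approx(f2.estimate, abs=1e-6)

    def test_matching_predictor_values(self):
        ests = self._estimates([2000, 2001, 2002, 2003], [-0.1, -0.05, 0.0, 0.05], [0.02] * 4)
        ts = {2000: 300.0, 2001: 320.0, 2002: 340.0, 2003: 360.0}
        fit = selection.weighted_trend(ests, "median_ts", ts)
        assert fit.estimate == pytest.approx(0.05 / 20.0, abs=1e-10)

    def test_nonpositive_se_rejected(self):
        ests = self._estimates([1, 2, 3], [0.0, 0.1, 0.2], [0.02, 0.02, 0.02])
        ests[0].slope_se = 0.0
        with pytest.raises(ValueError):
            selection.weighted_trend(ests, "year")

    def test_flagged_years_dropped(self):
        ests = self._estimates([1, 2, 3, 4], [0.0, 0.01, 0.02, 5.0], [0.02] * 4)
        ests[3].flag = "separation"
        fit = selection.weighted_trend(ests, "year")
        assert fit.n_years == 3


class TestSlopeInterceptCorrelation:
    def _est(self, year, slope, intercept):
        return SelectionEstimate(
            year=year, rate="fledglings", covariate_set="none",
            slope=slope, slope_se=0.02, intercept=intercept, n=30,
        )

    def test_exact_antisymmetry_gives_minus_one(self):
        ests = [self._est(y, -i, i) for y, i in zip(range(5), [1.0, 2, 3, 4, 5])]
        res = selection.slope_intercept_correlation(ests)
        assert res.r == pytest.approx(-1.0)

    def test_independent_values_near_zero(self):
        rng = np.random.default_rng(9)
        ests = [self._est(y, rng.normal(), rng.normal()) for y in range(1000)]
        res = selection.slope_intercept_correlation(ests)
        assert abs(res.r) < 0.1

    def test_deterioration_pattern_strongly_negative(self):
        # intercepts decline with year while late-season performance is held:
        # slope = (fixed_late - intercept)/span, an exact negative relation + noise
        rng = np.random.default_rng(4)
        ests = []
        for y in range(20):
            intercept = 2.0 - 0.08 * y + rng.normal(0, 0.05)
            slope = (0.5 - intercept) / 25.0 + rng.normal(0, 0.005)
            ests.append(self._est(y, slope, intercept))
        res = selection.slope_intercept_correlation(ests)
        assert res.r < -0.75


class TestLinearityCheck:
    def _weights_for(self, recs, y):
        return pd.DataFrame({"nest_id": recs["nest_id"], "nestling_age": 6, "weight": y})

    def test_linear_data_prefers_linear(self):
        rng = np.random.default_rng(11)
        prefer_linear = 0
        for rep in range(10):
            rel = np.tile(np.arange(0, 20), 3)
            y = 16.0 - 0.1 * rel + rng.normal(0, 0.6, len(rel))
            recs = year_records(rel, 1, "nest_success")
            check = selection.linearity_check(recs, 2000, "nestling_weight", self._weights_for(recs, y))
            prefer_linear += check.preferred == "linear"
        assert prefer_linear >= 8

    def test_strongly_quadratic_data_prefers_quadratic(self):
        rng = np.random.default_rng(12)
        rel = np.tile(np.arange(0, 20), 3)
        y = 14.0 + 0.5 * rel - 0.03 * rel**2 + rng.normal(0, 0.3, len(rel))
        recs = year_records(rel, 1, "nest_success")
        check = selection.linearity_check(recs, 2000, "nestling_weight", self._weights_for(recs, y))
        assert check.preferred == "quadratic"

    def test_small_year_skipped_with_flag(self):
        recs = year_records([0, 3, 6], [1, 0, 1], "nest_success")
        check = selection.linearity_check(recs, 2000, "nest_success")
        assert "skipped" in check.flag
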