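"""GLMM analysis surface: LRT, variance-partition R², bootstrap bands, reductions."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from wheatear_phenology import mixed
from wheatear_phenology.mixed import ModelSpec


def gaussian_frame(seed=0, n_year=20, per_year=40, beta_x=-0.13, sd_year=0.4, sd_terr=0.3, sd_resid=1.0):
    """Year-trend-like Gaussian data with two crossed grouping factors."""
    rng = np.random.default_rng(seed)
    n = n_year * per_year
    year = np.repeat(np.arange(n_year), per_year)
    terr = rng.integers(0, 60, n)
    covar = rng.normal(0, 1, n)
    u_y = rng.normal(0, sd_year, n_year)
    u_t = rng.normal(0, sd_terr, 60)
    y = 17.0 + beta_x * year + 0.5 * covar + u_y[year] + u_t[terr] + rng.normal(0, sd_resid, n)
    return pd.DataFrame({"resp": y, "year_c": year.astype(float), "covar": covar, "year": year, "terr": terr})


SPEC = ModelSpec(response="resp", family="gaussian", fixed=("year_c", "covar"), random=("year", "terr"), focal="year_c")


@pytest.fixture(scope="module")
def gaussian_fit():
    return mixed.fit_glmm(gaussian_frame(), SPEC)


class TestModelSpec:
    def test_focal_must_be_fixed_term(self):
        with pytest.raises(ValueError):
            ModelSpec("y", "gaussian", ("a",), ("g",), focal="b")

    def test_random_required(self):
        with pytest.raises(ValueError):
            ModelSpec("y", "gaussian", ("a",), (), focal="a")

    def test_drop_removes_term(self):
        reduced = SPEC.drop("covar")
        assert reduced.fixed == ("year_c",)


class TestFitGlmm:
    def test_planted_effects_recovered(self, gaussian_fit):
        coef = gaussian_fit.coefficients
        assert abs(coef.loc["year_c", "estimate"] - (-0.13)) < 2 * coef.loc["year_c", "se"]
        assert abs(coef.loc["covar", "estimate"] - 0.5) < 2 * coef.loc["covar", "se"]

    def test_variance_components_on_response_scale(self, gaussian_fit):
        assert set(gaussian_fit.random_variances) == {"year", "terr"}
        assert gaussian_fit.sigma2 == pytest.approx(1.0, rel=0.3)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            mixed.fit_glmm(gaussian_frame().drop(columns=["covar"]), SPEC)


class TestLrt:
    def test_identity_chisq_is_twice_delta_loglik(self, gaussian_fit):
        reduced = mixed.fit_glmm(gaussian_frame(), SPEC.drop("covar"))
        delta, chisq, df, p = mixed.lrt(gaussian_fit, reduced)
        assert chisq == pytest.approx(2 * delta)
        assert df == 1
        assert delta >= 0
        assert p < 0.05  # covar truly matters here

    def test_identical_models_give_zero_chisq_p_one(self, gaussian_fit):
        delta, chisq, df, p = mixed.lrt(gaussian_fit, gaussian_fit)
        assert chisq == 0.0
        assert p == 1.0

    def test_printed_delta_loglik_doubles_to_chisq(self):
        # the reporting convention: a log-likelihood drop of 8.4 is a chi-square of 16.8
        delta = 8.4
        assert 2 * delta == pytest.approx(16.8)

    def test_non_nested_rejected(self, gaussian_fit):
        other_spec = ModelSpec("resp", "gaussian", ("covar",), ("year", "terr"), focal="covar")
        other = mixed.fit_glmm(gaussian_frame(), other_spec)
        with pytest.raises(ValueError):
            mixed.lrt(other, gaussian_fit)

    def test_lrt_table_covers_fixed_terms(self, gaussian_fit):
        table = mixed.lrt_table(gaussian_fit)
        assert set(table.index) == {"year_c", "covar"}
        np.testing.assert_allclose(table["chisq"], 2 * table["delta_loglik"])

    def test_null_term_type_one_error_near_alpha(self):
        """LRT on a truly absent term rejects at ~5%: 300 quick null fits."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            n, n_g = 150, 15
            g = np.repeat(np.arange(n_g), n // n_g)
            y = rng.normal(0, 1, n) + rng.normal(0, 0.5, n_g)[g]
            x = rng.normal(0, 1, n)
            frame = pd.DataFrame({"resp": y, "x": x, "g": g})
            full = mixed.fit_glmm(frame, ModelSpec("resp", "gaussian", ("x",), ("g",), "x"))
            red = mixed.fit_glmm(frame, ModelSpec("resp", "gaussian", (), ("g",), ""))
            _, _, _, p = mixed.lrt(full, red)
            rejections += p < 0.05
        rate = rejections / n_sim
        ci = 2 * np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < ci + 0.01


class TestR2Nakagawa:
    def test_no_random_variance_equals_classical_r2(self):
        rng = np.random.default_rng(1)
        xb = rng.normal(0, 1, 80)
        yb = 1.0 + 0.8 * xb + rng.normal(0, 1, 80)
        frame = pd.DataFrame({"resp": np.tile(yb, 6), "x": np.tile(xb, 6), "g": np.repeat(np.arange(6), 80)})
        fit = mixed.fit_glmm(frame, ModelSpec("resp", "gaussian", ("x",), ("g",), "x"))
        ols = sm.OLS(np.tile(yb, 6), sm.add_constant(np.tile(xb, 6))).fit()
        assert fit.r2_marginal == pytest.approx(ols.rsquared, abs=1e-3)
        assert fit.r2_conditional == pytest.approx(fit.r2_marginal, abs=1e-6)

    def test_zero_fixed_effects_zero_marginal(self):
        rng = np.random.default_rng(2)
        g = np.repeat(np.arange(20), 20)
        y = rng.normal(0, 1, 400) + rng.normal(0, 1, 20)[g]
        frame = pd.DataFrame({"resp": y, "g": g})
        fit = mixed.fit_glmm(frame, ModelSpec("resp", "gaussian", (), ("g",), ""))
        assert fit.r2_marginal == pytest.approx(0.0, abs=1e-10)
        assert fit.r2_conditional > 0.2

    def test_analytic_variance_partition(self):
        """Planted variances 4 (fixed) : 1 (year) : 5 (residual) give R² 0.4 / 0.5."""
        rng = np.random.default_rng(3)
        n_year, per_year = 40, 50
        year = np.repeat(np.arange(n_year), per_year)
        x = rng.normal(0, 1, n_year * per_year)
        y = 2.0 * x + rng.normal(0, 1.0, n_year)[year] + rng.normal(0, np.sqrt(5), n_year * per_year)
        frame = pd.DataFrame({"resp": y, "x": x, "g": year})
        fit = mixed.fit_glmm(frame, ModelSpec("resp", "gaussian", ("x",), ("g",), "x"))
        assert fit.r2_marginal == pytest.approx(0.4, abs=0.05)
        assert fit.r2_conditional == pytest.approx(0.5, abs=0.05)

    def test_ordering_invariant(self, gaussian_fit):
        assert 0 <= gaussian_fit.r2_marginal
        assert gaussian_fit.r2_marginal <= gaussian_fit.r2_conditional <= 1


class TestBootstrapPredictions:
    def test_fixed_seed_reproducible(self, gaussian_fit):
        grid = np.array([0.0, 10.0, 19.0])
        b1 = mixed.bootstrap_predictions(gaussian_fit, grid, n_boot=8, seed=5)
        b2 = mixed.bootstrap_predictions(gaussian_fit, grid, n_boot=8, seed=5)
        np.testing.assert_array_equal(b1.median, b2.median)
        np.testing.assert_array_equal(b1.lower, b2.lower)

    def test_single_replicate_band_collapses(self, gaussian_fit):
        grid = np.array([0.0, 19.0])
        band = mixed.bootstrap_predictions(gaussian_fit, grid, n_boot=1, seed=2)
        np.testing.assert_allclose(band.lower, band.upper)
        np.testing.assert_allclose(band.lower, band.median)

    def test_band_ordering_and_trend_coverage(self, gaussian_fit):
        grid = np.linspace(0, 19, 5)
        band = mixed.bootstrap_predictions(gaussian_fit, grid, n_boot=30, seed=7)
        assert (band.lower <= band.median).all() and (band.median <= band.upper).all()
        truth = 17.0 - 0.13 * grid  # planted fixed-effect curve (covar at ~0 mean)
        inside = (truth >= band.lower - 0.3) & (truth <= band.upper + 0.3)
        assert inside.all()


class TestReductions:
    @pytest.mark.parametrize(
        "start, end, expected",
        [(0.92, 0.71, 23), (17.5, 14.7, 16), (4.68, 3.13, 33), (0.99, 0.21, 79)],
    )
    def test_percent_reduction_examples(self, start, end, expected):
        assert round(mixed.relative_reduction(start, end)) == expected

    @pytest.mark.parametrize("start, end, expected", [(0.54, 0.38, 29), (0.54, 0.45, 16)])
    def test_percent_reduction_survival_within_rounding(self, start, end, expected):
        # survival endpoints are reported to 2 decimals only; allow the
        # rounding slack that implies on the percentage
        assert abs(mixed.relative_reduction(start, end) - expected) <= 1.0

    def test_zero_start_rejected(self):
        with pytest.raises(ValueError):
            mixed.relative_reduction(0.0, 1.0)

    def test_trend_endpoints_feed_reduction(self, gaussian_fit):
        start, end = mixed.trend_endpoints(gaussian_fit, 0.0, 19.0)
        assert start > end  # declining planted trend
        red = mixed.relative_reduction(start, end)
        assert red == pytest.approx(100 * 0.13 * 19 / start, abs=3.0)
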