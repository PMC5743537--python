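"""Mixed-model engine against independent likelihood oracles.

Two oracle routes: a dense multivariate-normal likelihood evaluated from
first principles (self-contained), and R's lme4 via Rscript (independent
implementation of the same estimators).
"""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from wheatear_phenology.glmm import (
    GeneralizedLinearMixedModel,
    LinearMixedModel,
    RandomStructure,
)


def simulate_lmm(seed=42, n=300, n_year=15, n_terr=40, sd_year=0.8, sd_terr=0.5, sd_resid=1.0):
    rng = np.random.default_rng(seed)
    year = rng.integers(0, n_year, n)
    terr = rng.integers(0, n_terr, n)
    x = rng.normal(0, 1, n)
    u_y = rng.normal(0, sd_year, n_year)
    u_t = rng.normal(0, sd_terr, n_terr)
    y = 2.0 + 1.5 * x + u_y[year] + u_t[terr] + rng.normal(0, sd_resid, n)
    frame = pd.DataFrame({"y": y, "x": x, "year": year, "terr": terr})
    struct = RandomStructure.from_frame(frame, ["year", "terr"])
    X = np.column_stack([np.ones(n), x])
    return frame, X, y, struct


class TestLinearMixedModel:
    def test_profiled_loglik_matches_dense_mvn_oracle(self):
        frame, X, y, struct = simulate_lmm()
        fit = LinearMixedModel(X, y, struct).fit()
        Z = struct.Z.toarray()
        G = np.diag(struct.expand(fit.variances))
        V = Z @ G @ Z.T + fit.sigma2 * np.eye(len(y))
        oracle = stats.multivariate_normal.logpdf(y, mean=X @ fit.beta, cov=V)
        assert fit.loglik == pytest.approx(oracle, abs=1e-6)
        # GLS fixed effects at the fitted variances, dense route
        Vi = np.linalg.inv(V)
        beta_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        np.testing.assert_allclose(fit.beta, beta_gls, atol=1e-8)

    def test_fitted_variances_recover_planted_magnitudes(self):
        frame, X, y, struct = simulate_lmm(seed=5, n=2000, n_year=30, n_terr=80)
        fit = LinearMixedModel(X, y, struct).fit()
        assert fit.variances[0] == pytest.approx(0.64, rel=0.8)  # sd 0.8 planted
        assert fit.sigma2 == pytest.approx(1.0, rel=0.25)

    def test_reml_variance_not_smaller_than_ml(self):
        frame, X, y, struct = simulate_lmm(seed=6)
        ml = LinearMixedModel(X, y, struct).fit(reml=False)
        reml = LinearMixedModel(X, y, struct).fit(reml=True)
        assert reml.sigma2 >= ml.sigma2 * 0.99

    def test_zero_random_variance_reduces_to_ols(self):
        # identical data block replicated across groups: between-group
        # variance is exactly zero, so the MLE sits at the boundary and the
        # fit must coincide with plain OLS
        rng = np.random.default_rng(8)
        xb = rng.normal(0, 1, 50)
        yb = 1.0 + 0.5 * xb + rng.normal(0, 1, 50)
        G = 8
        frame = pd.DataFrame({"g": np.repeat(np.arange(G), 50)})
        x, y = np.tile(xb, G), np.tile(yb, G)
        struct = RandomStructure.from_frame(frame, ["g"])
        X = np.column_stack([np.ones(len(y)), x])
        fit = LinearMixedModel(X, y, struct).fit()
        ols = sm.OLS(y, X).fit()
        assert fit.boundary.all()
        np.testing.assert_allclose(fit.beta, ols.params, atol=1e-4)

    def test_loglik_never_decreases_with_added_covariate(self):
        frame, X, y, struct = simulate_lmm(seed=10)
        rng = np.random.default_rng(0)
        X2 = np.column_stack([X, rng.normal(size=len(y))])  # irrelevant covariate
        ll1 = LinearMixedModel(X, y, struct).fit().loglik
        ll2 = LinearMixedModel(X2, y, struct).fit().loglik
        assert ll2 >= ll1 - 1e-6


class TestLaplaceGlmm:
    def _simulate(self, family, seed=7, n=600):
        rng = np.random.default_rng(seed)
        year = rng.integers(0, 20, n)
        terr = rng.integers(0, 50, n)
        x = rng.normal(0, 1, n)
        u_y = rng.normal(0, 0.6, 20)
        u_t = rng.normal(0, 0.4, 50)
        if family == "binomial":
            eta = 0.5 - 0.8 * x + u_y[year] + u_t[terr]
            y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        else:
            eta = 0.8 + 0.3 * x + 0.5 * u_y[year] + 0.5 * u_t[terr]
            y = rng.poisson(np.exp(eta)).astype(float)
        frame = pd.DataFrame({"y": y, "x": x, "year": year, "terr": terr})
        struct = RandomStructure.from_frame(frame, ["year", "terr"])
        X = np.column_stack([np.ones(n), x])
        return frame, X, y, struct

    @pytest.mark.parametrize("family, planted", [("binomial", -0.8), ("poisson", 0.3)])
    def test_planted_fixed_effect_recovered(self, family, planted):
        frame, X, y, struct = self._simulate(family)
        fit = GeneralizedLinearMixedModel(X, y, struct, family).fit()
        se = np.sqrt(fit.vcov_beta[1, 1])
        assert abs(fit.beta[1] - planted) < 2 * se

    @pytest.mark.parametrize("family", ["binomial", "poisson"])
    def test_zero_random_variance_reduces_to_glm(self, family):
        # identical data block per group (see the Gaussian analogue above)
        rng = np.random.default_rng(13)
        xb = rng.normal(0, 1, 60)
        if family == "binomial":
            yb = rng.binomial(1, 1 / (1 + np.exp(-(0.3 + 0.6 * xb)))).astype(float)
            glm_family = sm.families.Binomial()
        else:
            yb = rng.poisson(np.exp(0.5 + 0.3 * xb)).astype(float)
            glm_family = sm.families.Poisson()
        G = 8
        frame = pd.DataFrame({"g": np.repeat(np.arange(G), 60)})
        x, y = np.tile(xb, G), np.tile(yb, G)
        struct = RandomStructure.from_frame(frame, ["g"])
        X = np.column_stack([np.ones(len(y)), x])
        fit = GeneralizedLinearMixedModel(X, y, struct, family).fit()
        glm = sm.GLM(y, X, family=glm_family).fit()
        np.testing.assert_allclose(fit.beta, glm.params, atol=1e-4)
        assert fit.boundary.all()  # the variance collapses to the zero boundary

    def test_unsupported_family_rejected(self):
        frame, X, y, struct = self._simulate("binomial")
        with pytest.raises(ValueError):
            GeneralizedLinearMixedModel(X, y, struct, "gamma")


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
class TestAgainstLme4:
    """Independent-implementation oracle: the same models fitted by lme4."""

    def _run_r(self, script, tmp_path):
        rfile = tmp_path / "check.R"
        rfile.write_text(script)
        res = subprocess.run(
            ["Rscript", "--vanilla", str(rfile)], capture_output=True, text=True, timeout=240
        )
        assert res.returncode == 0, res.stderr
        return json.loads(res.stdout.strip().splitlines()[-1])

    def test_gaussian_ml_matches_lmer(self, tmp_path):
        frame, X, y, struct = simulate_lmm(seed=42)
        fit = LinearMixedModel(X, y, struct).fit()
        csv = tmp_path / "d.csv"
        frame.to_csv(csv, index=False)
        out = self._run_r(
            f"""
            suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
            d <- read.csv("{csv}")
            m <- lmer(y ~ x + (1|year) + (1|terr), data=d, REML=FALSE)
            cat(toJSON(list(beta=as.numeric(fixef(m)), loglik=as.numeric(logLik(m))), digits=10))
            """,
            tmp_path,
        )
        np.testing.assert_allclose(fit.beta, out["beta"], atol=1e-5)
        assert fit.loglik == pytest.approx(out["loglik"][0], abs=1e-4)

    def test_binomial_laplace_matches_glmer_joint_mode(self, tmp_path):
        rng = np.random.default_rng(7)
        n = 500
        year = rng.integers(0, 18, n)
        terr = rng.integers(0, 40, n)
        x = rng.normal(0, 1, n)
        eta = 0.4 - 0.7 * x + rng.normal(0, 0.6, 18)[year] + rng.normal(0, 0.4, 40)[terr]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        frame = pd.DataFrame({"y": y, "x": x, "year": year, "terr": terr})
        struct = RandomStructure.from_frame(frame, ["year", "terr"])
        X = np.column_stack([np.ones(n), x])
        fit = GeneralizedLinearMixedModel(X, y, struct, "binomial").fit()
        csv = tmp_path / "d.csv"
        frame.to_csv(csv, index=False)
        out = self._run_r(
            f"""
            suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
            d <- read.csv("{csv}")
            m <- glmer(y ~ x + (1|year) + (1|terr), data=d, family=binomial, nAGQ=0)
            cat(toJSON(list(beta=as.numeric(fixef(m)), loglik=as.numeric(logLik(m))), digits=10))
            """,
            tmp_path,
        )
        np.testing.assert_allclose(fit.beta, out["beta"], atol=5e-3)
        assert fit.loglik == pytest.approx(out["loglik"][0], abs=5e-3)
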