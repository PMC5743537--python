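"""Random-intercept GLMMs for demographic rates and nestling weight.

Models follow the two structures used throughout the analysis:

* **trend models** — ``rate ~ year + lay date + female age + rain + density
  (+ nest success for survival; + nestling age + brood size for weight)``
  with crossed random intercepts for year, territory and individual;
* **matching models** — the same but with the annual median thermal sum at
  breeding as the focal predictor and the individual thermal sum replacing
  lay date.

Fixed-effect p-values come from Wald z tests (non-Gaussian) or
likelihood-ratio tests (Gaussian, both models fitted by ML).  Variance
explained is partitioned into marginal R² (fixed effects) and conditional
R² (fixed plus random effects).  Prediction bands use a seeded parametric
bootstrap: parameters are drawn from their asymptotic distribution,
responses re-simulated, the model refitted, and pointwise 2.5/50/97.5
percentiles taken on the focal-predictor grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma

from wheatear_phenology.glmm import (
    ConvergenceError,
    GeneralizedLinearMixedModel,
    LinearMixedModel,
    MixedFitResult,
    RandomStructure,
)

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "BootstrapBand",
    "fit_glmm",
    "lrt",
    "lrt_table",
    "r2_nakagawa",
    "bootstrap_predictions",
    "relative_reduction",
    "trend_endpoints",
]


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one GLMM.

    ``fixed`` are column names in the model frame (numeric, already
    encoded); ``random`` are grouping-factor column names; ``focal`` must be
    among the fixed terms.
    """

    response: str
    family: str  # gaussian | binomial | poisson
    fixed: tuple[str, ...]
    random: tuple[str, ...]
    focal: str

    def __post_init__(self) -> None:
        if self.focal and self.focal not in self.fixed:
            raise ValueError(f"focal term {self.focal!r} not among fixed terms")
        if not self.random:
            raise ValueError("at least one random grouping factor is required")
        if self.family not in ("gaussian", "binomial", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")

    def drop(self, term: str) -> "ModelSpec":
        if term not in self.fixed:
            raise ValueError(f"{term!r} not in fixed terms")
        fixed = tuple(t for t in self.fixed if t != term)
        focal = self.focal if self.focal != term else (fixed[0] if fixed else "")
        return ModelSpec(self.response, self.family, fixed, self.random, focal)


@dataclass
class MixedModelFit:
    """Fitted GLMM: coefficient table, variance components, likelihood."""

    spec: ModelSpec
    coefficients: pd.DataFrame  # index: term; columns: estimate, se, stat, p
    random_variances: dict[str, float]
    sigma2: float
    loglik: float
    n: int
    converged: bool
    boundary: dict[str, bool]
    r2_marginal: float = np.nan
    r2_conditional: float = np.nan
    # retained model internals for LRT refits, R² and the bootstrap
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    struct: RandomStructure = field(repr=False, default=None)
    data: pd.DataFrame = field(repr=False, default=None)
    raw: MixedFitResult = field(repr=False, default=None)

    @property
    def params(self) -> pd.Series:
        return self.coefficients["estimate"]

    def predict_fixed(self, X: np.ndarray) -> np.ndarray:
        """Mean response from fixed effects alone (population level)."""
        eta = X @ self.coefficients["estimate"].to_numpy()
        return _inverse_link(self.spec.family, eta)


def _inverse_link(family: str, eta: np.ndarray) -> np.ndarray:
    if family == "binomial":
        return 1.0 / (1.0 + np.exp(-eta))
    if family == "poisson":
        return np.exp(eta)
    return eta


def _design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, RandomStructure]:
    missing = [c for c in (spec.response, *spec.fixed, *spec.random) if c not in data.columns]
    if missing:
        raise ValueError(f"model frame missing columns: {missing}")
    X = np.column_stack([np.ones(len(data))] + [data[t].to_numpy(dtype=float) for t in spec.fixed])
    y = data[spec.response].to_numpy(dtype=float)
    struct = RandomStructure.from_frame(data, list(spec.random))
    return X, y, struct


def fit_glmm(data: pd.DataFrame, spec: ModelSpec, reml: bool = False) -> MixedModelFit:
    """Fit one GLMM by (Laplace-approximated) maximum likelihood.

    Gaussian responses use exact profiled ML (or REML when requested for
    variance reporting); binomial and Poisson responses use the Laplace
    approximation.  A variance component estimated at the zero boundary is
    flagged, not an error.
    """
    X, y, struct = _design(data, spec)
    if spec.family == "gaussian":
        raw = LinearMixedModel(X, y, struct).fit(reml=reml)
    else:
        if reml:
            raise ValueError("REML is only defined for the Gaussian model here")
        raw = GeneralizedLinearMixedModel(X, y, struct, spec.family).fit()
    if not raw.converged:
        raise ConvergenceError(f"GLMM for {spec.response!r} did not converge", raw.trace)
    se = np.sqrt(np.diag(raw.vcov_beta))
    stat = raw.beta / se
    if spec.family == "gaussian":
        # Wald t with residual-like df; LRT is the preferred test for these models
        dof = max(len(y) - X.shape[1], 1)
        p = 2 * stats.t.sf(np.abs(stat), dof)
    else:
        p = 2 * stats.norm.sf(np.abs(stat))
    coef = pd.DataFrame(
        {"estimate": raw.beta, "se": se, "stat": stat, "p": p},
        index=pd.Index(["intercept", *spec.fixed], name="term"),
    )
    fit = MixedModelFit(
        spec=spec,
        coefficients=coef,
        random_variances=dict(zip(struct.names, raw.variances)),
        sigma2=raw.sigma2,
        loglik=raw.loglik,
        n=len(y),
        converged=raw.converged,
        boundary=dict(zip(struct.names, raw.boundary)),
        X=X,
        y=y,
        struct=struct,
        data=data,
        raw=raw,
    )
    fit.r2_marginal, fit.r2_conditional = r2_nakagawa(fit)
    return fit


def lrt(full: MixedModelFit, reduced: MixedModelFit) -> tuple[float, float, int, float]:
    """Likelihood-ratio test of nested ML fits.

    Returns ``(delta_loglik, chisq, df, p)`` with ``chisq = 2·delta_loglik``
    and df equal to the fixed-parameter difference.
    """
    if not set(reduced.spec.fixed) <= set(full.spec.fixed):
        raise ValueError("reduced model fixed terms are not a subset of the full model's")
    if reduced.spec.random != full.spec.random or reduced.n != full.n:
        raise ValueError("LRT requires the same data and random structure")
    df = len(full.spec.fixed) - len(reduced.spec.fixed)
    delta = full.loglik - reduced.loglik
    chisq = 2.0 * delta
    p = float(stats.chi2.sf(max(chisq, 0.0), df)) if df > 0 else 1.0
    return float(delta), float(chisq), df, p


def lrt_table(fit: MixedModelFit) -> pd.DataFrame:
    """Single-term deletion LRTs (df = 1 each) for every fixed term."""
    rows = []
    for term in fit.spec.fixed:
        reduced = fit_glmm(fit.data, fit.spec.drop(term)) if len(fit.spec.fixed) > 1 else None
        if reduced is None:
            continue
        delta, chisq, df, p = lrt(fit, reduced)
        rows.append({"term": term, "delta_loglik": delta, "chisq": chisq, "df": df, "p": p})
    return pd.DataFrame(rows).set_index("term")


def r2_nakagawa(fit: MixedModelFit) -> tuple[float, float]:
    """Variance-partition (marginal, conditional) R².

    marginal = var(fixed) / (var(fixed) + var(random) + var(residual)),
    conditional adds var(random) to the numerator.  The distribution-specific
    residual variance is the residual variance (Gaussian), π²/3 (binomial,
    logit) or the trigamma function at the expected marginal rate (Poisson,
    log).
    """
    eta_fixed = fit.X @ fit.coefficients["estimate"].to_numpy()
    var_f = float(np.var(eta_fixed))
    var_r = float(sum(fit.random_variances.values()))
    fam = fit.spec.family
    if fam == "gaussian":
        var_d = fit.sigma2
    elif fam == "binomial":
        var_d = np.pi**2 / 3.0
    else:  # poisson, log link
        lam = float(np.exp(np.mean(eta_fixed) + 0.5 * var_r))
        var_d = float(polygamma(1, max(lam, 1e-8)))
    total = var_f + var_r + var_d
    return var_f / total, (var_f + var_r) / total


@dataclass
class BootstrapBand:
    """Pointwise parametric-bootstrap prediction band on the focal grid."""

    grid: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_boot: int
    n_failed: int
    seed: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"focal": self.grid, "lower": self.lower, "median": self.median, "upper": self.upper})


def _simulate_response(fit: MixedModelFit, beta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    struct = fit.struct
    u = np.concatenate(
        [rng.normal(0.0, np.sqrt(max(fit.random_variances[name], 0.0)), q) for name, q in zip(struct.names, struct.n_levels)]
    )
    eta = fit.X @ beta + struct.Z @ u
    fam = fit.spec.family
    if fam == "gaussian":
        return eta + rng.normal(0.0, np.sqrt(fit.sigma2), len(eta))
    if fam == "binomial":
        return rng.binomial(1, _inverse_link(fam, eta)).astype(float)
    return rng.poisson(_inverse_link(fam, eta)).astype(float)


def _grid_design(fit: MixedModelFit, grid: np.ndarray) -> np.ndarray:
    """Design on the focal grid with all other covariates at their means."""
    terms = list(fit.spec.fixed)
    focal_idx = terms.index(fit.spec.focal)
    means = fit.X[:, 1:].mean(axis=0)
    Xg = np.tile(np.concatenate([[1.0], means]), (len(grid), 1))
    Xg[:, 1 + focal_idx] = grid
    return Xg


def bootstrap_predictions(
    fit: MixedModelFit,
    grid: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    max_failure_rate: float = 0.2,
) -> BootstrapBand:
    """Parametric-bootstrap band for the fixed-effect response curve.

    Each replicate draws β* from N(β̂, V̂), re-simulates the response from
    the fitted model (fresh random intercepts, family noise), refits, and
    predicts on the focal grid.  Replicates whose refit fails are skipped;
    more than ``max_failure_rate`` failures raise.
    """
    rng = np.random.default_rng(seed)
    grid = np.asarray(grid, dtype=float)
    Xg = _grid_design(fit, grid)
    beta_hat = fit.coefficients["estimate"].to_numpy()
    preds, failed = [], 0
    for _ in range(n_boot):
        beta_star = rng.multivariate_normal(beta_hat, fit.raw.vcov_beta, method="cholesky")
        y_star = _simulate_response(fit, beta_star, rng)
        sim = fit.data.copy()
        sim[fit.spec.response] = y_star
        try:
            refit = fit_glmm(sim, fit.spec)
        except (ConvergenceError, np.linalg.LinAlgError, ValueError):
            failed += 1
            continue
        preds.append(refit.predict_fixed(Xg))
    if failed > max_failure_rate * n_boot:
        raise ConvergenceError(f"parametric bootstrap: {failed}/{n_boot} refits failed")
    arr = np.array(preds)
    lo, med, hi = np.percentile(arr, [2.5, 50.0, 97.5], axis=0)
    return BootstrapBand(grid=grid, median=med, lower=lo, upper=hi, n_boot=n_boot, n_failed=failed, seed=seed)


def relative_reduction(start: float, end: float) -> float:
    """Percent reduction of a rate relative to its value at the start.

    ``100 · (start − end) / start``; e.g. a decline from 0.92 to 0.71
    is a 23% reduction.
    """
    if start == 0:
        raise ValueError("relative reduction undefined for a zero starting value")
    return 100.0 * (start - end) / start


def trend_endpoints(fit: MixedModelFit, focal_start: float, focal_end: float) -> tuple[float, float]:
    """Predicted response at the focal predictor's start and end values.

    Other covariates are held at their sample means; predictions are on the
    response scale, so the pair feeds :func:`relative_reduction` directly.
    """
    Xg = _grid_design(fit, np.array([focal_start, focal_end]))
    start, end = fit.predict_fixed(Xg)
    return float(start), float(end)
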