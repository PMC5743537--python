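"""Mixed-model estimation with crossed random intercepts.

Two estimators sharing one data representation:

* :class:`LinearMixedModel` — Gaussian responses, exact maximum likelihood
  with the fixed effects and residual variance profiled out, leaving a
  low-dimensional optimization over log variance ratios.  ML is the default
  so likelihood-ratio tests on fixed effects are valid; REML is available
  for variance reporting.
* :class:`GeneralizedLinearMixedModel` — Bernoulli/logit and Poisson/log
  responses via the Laplace approximation, with the joint (β, u) mode found
  by penalized iteratively reweighted least squares.

Crossed grouping factors (e.g. year × territory × individual) are handled
through the q×q system ``Z'WZ + G⁻¹`` (q = total random-effect levels),
assembled from a sparse indicator matrix Z, so cost scales with the number
of levels rather than observations.  With several hundred levels the dense
Cholesky of that system is the dominant cost and remains cheap.

Only random intercepts are supported — no random slopes, by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.linalg import splu

__all__ = ["RandomStructure", "LinearMixedModel", "GeneralizedLinearMixedModel", "ConvergenceError"]

LOG_RATIO_MIN = -14.0  # variance (ratio) below ~8e-7 is treated as boundary zero
LOG_RATIO_MAX = 10.0
BOUNDARY_TOL = -12.0


_SPARSE_Q_THRESHOLD = 250  # above this many random-effect levels, use sparse LU


class _SymSolver:
    """Solve with and take the log-determinant of an SPD q×q system.

    Dense Cholesky for small q; sparse LU (the system is sparse for crossed
    intercepts) once the level count makes dense factorization the
    bottleneck.
    """

    def __init__(self, M):
        if sparse.issparse(M):
            if M.shape[0] <= _SPARSE_Q_THRESHOLD:
                self._dense = cho_factor(M.toarray(), lower=True)
                self._lu = None
            else:
                self._lu = splu(M.tocsc(), permc_spec="MMD_AT_PLUS_A")
                self._dense = None
        else:
            self._dense = cho_factor(M, lower=True)
            self._lu = None

    def solve(self, B: np.ndarray) -> np.ndarray:
        if self._lu is not None:
            return self._lu.solve(np.asarray(B, dtype=float))
        return cho_solve(self._dense, B)

    def logdet(self) -> float:
        if self._lu is not None:
            # M is SPD: |det| = prod |diag(U)|; permutation signs cancel in abs
            return float(np.log(np.abs(self._lu.U.diagonal())).sum())
        return 2.0 * float(np.log(np.diag(self._dense[0])).sum())


class ConvergenceError(RuntimeError):
    """Mixed-model optimization failed; carries the iteration trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class RandomStructure:
    """Crossed random-intercept design built from integer level codes."""

    names: list[str]
    codes: list[np.ndarray]
    n_levels: list[int] = field(default_factory=list)
    Z: sparse.csr_matrix = field(default=None, repr=False)

    @classmethod
    def from_frame(cls, frame, factors: list[str]) -> "RandomStructure":
        names, codes, n_levels = [], [], []
        for f in factors:
            c, uniques = frame[f].factorize()
            if len(uniques) < 2:
                raise ValueError(f"grouping factor {f!r} has fewer than 2 levels")
            names.append(f)
            codes.append(np.asarray(c, dtype=np.int64))
            n_levels.append(len(uniques))
        return cls(names=names, codes=codes, n_levels=n_levels)

    def __post_init__(self) -> None:
        if not self.n_levels:
            self.n_levels = [int(c.max()) + 1 for c in self.codes]
        n = len(self.codes[0])
        offset = 0
        rows = np.arange(n)
        cols = []
        for c, q in zip(self.codes, self.n_levels):
            cols.append(c + offset)
            offset += q
        col = np.concatenate(cols)
        row = np.tile(rows, len(self.codes))
        data = np.ones(len(col))
        self.Z = sparse.csr_matrix((data, (row, col)), shape=(n, offset))

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def q_total(self) -> int:
        return self.Z.shape[1]

    def expand(self, per_factor: np.ndarray) -> np.ndarray:
        """Repeat one value per factor across that factor's levels (length q_total)."""
        return np.concatenate([np.full(q, v) for v, q in zip(per_factor, self.n_levels)])


@dataclass
class MixedFitResult:
    """Raw estimator output (family-agnostic)."""

    beta: np.ndarray
    vcov_beta: np.ndarray
    variances: np.ndarray  # per-factor random-intercept variances, response/link scale
    sigma2: float  # residual variance (Gaussian; nan otherwise)
    loglik: float
    u: np.ndarray  # BLUPs / conditional modes, concatenated per factor
    converged: bool
    boundary: np.ndarray  # per-factor flags: variance at zero boundary
    n_iter: int
    trace: list = field(default_factory=list, repr=False)


def _neg_loglik_gaussian(delta, X, y, ZtZ, ZtX, Zty, struct, reml):
    """Profiled −2·loglik at log variance ratios ``delta``."""
    n, p = X.shape
    gamma = np.exp(delta)
    ginv = struct.expand(1.0 / gamma)
    M = ZtZ + sparse.diags(ginv)
    try:
        solver = _SymSolver(M)
    except (np.linalg.LinAlgError, RuntimeError):
        return np.inf, None
    # V0^{-1}A = A - Z M^{-1} Z'A  computed through the q-dim system
    MiZtX = solver.solve(ZtX)
    MiZty = solver.solve(Zty)
    XtViX = X.T @ X - ZtX.T @ MiZtX
    XtViy = X.T @ y - ZtX.T @ MiZty
    ytViy = y @ y - Zty @ MiZty
    try:
        cXX = cho_factor(XtViX, lower=True)
    except np.linalg.LinAlgError:
        return np.inf, None
    beta = cho_solve(cXX, XtViy)
    rss = ytViy - XtViy @ beta  # r'V0^{-1}r for r = y - Xb (GLS identity)
    rss = max(rss, 1e-300)
    logdetV0 = solver.logdet() + float(np.dot(struct.n_levels, delta))
    if reml:
        sigma2 = rss / (n - p)
        logdetXX = 2.0 * np.log(np.diag(cXX[0])).sum()
        m2ll = (n - p) * np.log(2 * np.pi * sigma2) + (n - p) + logdetV0 + logdetXX
    else:
        sigma2 = rss / n
        m2ll = n * np.log(2 * np.pi * sigma2) + n + logdetV0
    aux = (beta, sigma2, solver, cXX, gamma)
    return m2ll, aux


class LinearMixedModel:
    """Gaussian mixed model with crossed random intercepts.

    Parameters
    ----------
    X : (n, p) design matrix including the constant.
    y : (n,) response.
    struct : RandomStructure
        Crossed random-intercept layout.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, struct: RandomStructure):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.struct = struct
        Z = struct.Z
        self._ZtZ = (Z.T @ Z).tocsr()
        self._ZtX = Z.T @ self.X
        self._Zty = Z.T @ self.y

    def fit(self, reml: bool = False, start: np.ndarray | None = None) -> MixedFitResult:
        k = self.struct.k
        trace: list = []

        def objective(delta):
            delta = np.clip(delta, LOG_RATIO_MIN, LOG_RATIO_MAX)
            val, _ = _neg_loglik_gaussian(delta, self.X, self.y, self._ZtZ, self._ZtX, self._Zty, self.struct, reml)
            trace.append((delta.copy(), val))
            return val

        x0 = np.full(k, -1.0) if start is None else np.asarray(start, dtype=float)
        if k == 1:
            res = optimize.minimize_scalar(
                lambda d: objective(np.array([d])), bounds=(LOG_RATIO_MIN, LOG_RATIO_MAX), method="bounded",
                options={"xatol": 1e-8},
            )
            delta = np.clip(np.array([res.x]), LOG_RATIO_MIN, LOG_RATIO_MAX)
            success = res.success
        else:
            res = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 1500, "adaptive": True},
            )
            delta = np.clip(res.x, LOG_RATIO_MIN, LOG_RATIO_MAX)
            success = res.success or res.fun < np.inf
        m2ll, aux = _neg_loglik_gaussian(delta, self.X, self.y, self._ZtZ, self._ZtX, self._Zty, self.struct, reml)
        if aux is None:
            raise ConvergenceError("variance optimization produced a singular system", trace)
        beta, sigma2, solver, cXX, gamma = aux
        resid_part = self.y - self.X @ beta
        u = solver.solve(self.struct.Z.T @ resid_part)
        vcov_beta = sigma2 * cho_solve(cXX, np.eye(self.X.shape[1]))
        return MixedFitResult(
            beta=beta,
            vcov_beta=vcov_beta,
            variances=gamma * sigma2,
            sigma2=float(sigma2),
            loglik=-0.5 * m2ll,
            u=u,
            converged=bool(success),
            boundary=delta <= BOUNDARY_TOL,
            n_iter=len(trace),
            trace=trace,
        )


# ---------------------------------------------------------------------------
# Laplace GLMM


def _family_funcs(family: str):
    if family == "binomial":

        def mu_of_eta(eta):
            return 1.0 / (1.0 + np.exp(-eta))

        def weights(mu):
            return np.clip(mu * (1 - mu), 1e-10, None)

        def loglik(y, mu):
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))

    elif family == "poisson":

        def mu_of_eta(eta):
            return np.exp(np.clip(eta, -30, 30))

        def weights(mu):
            return np.clip(mu, 1e-10, None)

        def loglik(y, mu):
            from scipy.special import gammaln

            mu = np.clip(mu, 1e-12, None)
            return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))

    else:
        raise ValueError(f"unsupported GLMM family {family!r}")
    return mu_of_eta, weights, loglik


class GeneralizedLinearMixedModel:
    """Laplace-approximated ML for Bernoulli/logit and Poisson/log responses.

    For fixed random-intercept variances the joint mode of (β, u) is found
    by penalized IRLS; the Laplace log-likelihood

        ℓ ≈ Σ log f(y|û) − ½ û'G⁻¹û − ½ log|G·Z'WZ + I|

    is then maximized over log variances with Nelder–Mead.  This joint-mode
    variant corresponds to lme4's fast ``nAGQ=0`` approximation.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, struct: RandomStructure, family: str):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.struct = struct
        self.family = family
        self._mu_of_eta, self._weights, self._loglik = _family_funcs(family)

    def _pirls(self, sigma2: np.ndarray, beta0, u0, max_iter: int = 80, tol: float = 1e-9):
        X, y, Z = self.X, self.y, self.struct.Z
        n, p = X.shape
        ginv = self.struct.expand(1.0 / np.clip(sigma2, 1e-12, None))
        beta = np.zeros(p) if beta0 is None else beta0.copy()
        u = np.zeros(self.struct.q_total) if u0 is None else u0.copy()
        last = np.inf
        aux = None
        for it in range(max_iter):
            eta = X @ beta + Z @ u
            mu = self._mu_of_eta(eta)
            w = self._weights(mu)
            z = eta + (y - mu) / w
            Wsq = sparse.diags(np.sqrt(w))
            ZW = Wsq @ Z
            XW = np.sqrt(w)[:, None] * X
            Mq = (ZW.T @ ZW) + sparse.diags(ginv)
            ZtWX = ZW.T @ XW
            zw = np.sqrt(w) * z
            ZtWz = ZW.T @ zw
            XtWz = XW.T @ zw
            solver = _SymSolver(Mq)
            MiZtWX = solver.solve(ZtWX)
            MiZtWz = solver.solve(ZtWz)
            S = XW.T @ XW - ZtWX.T @ MiZtWX
            rhs = XtWz - ZtWX.T @ MiZtWz
            cS = cho_factor(S, lower=True)
            beta = cho_solve(cS, rhs)
            u = MiZtWz - MiZtWX @ beta
            pen = self._loglik(y, self._mu_of_eta(X @ beta + Z @ u)) - 0.5 * float(u @ (ginv * u))
            aux = (solver, cS, u, beta, w)
            if abs(pen - last) < tol * (abs(pen) + 1.0):
                last = pen
                break
            last = pen
        return beta, u, last, aux

    def _laplace_m2ll(self, log_sigma2: np.ndarray, state: dict):
        sigma2 = np.exp(np.clip(log_sigma2, LOG_RATIO_MIN, LOG_RATIO_MAX))
        try:
            beta, u, pen, aux = self._pirls(sigma2, state.get("beta"), state.get("u"))
        except (np.linalg.LinAlgError, RuntimeError):
            return np.inf, None
        solver, cS, u, beta, w = aux
        # log|G Z'WZ + I| = log|Z'WZ + G^{-1}| + log|G|
        logdet = solver.logdet() + float(
            np.dot(self.struct.n_levels, np.log(np.clip(sigma2, 1e-300, None)))
        )
        m2ll = -2.0 * pen + logdet
        state["beta"], state["u"] = beta, u
        return m2ll, (beta, u, cS, sigma2)

    def fit(self, start: np.ndarray | None = None) -> MixedFitResult:
        k = self.struct.k
        state: dict = {}
        trace: list = []

        def objective(ls):
            val, _ = self._laplace_m2ll(ls, state)
            trace.append((np.array(ls, copy=True), val))
            return val

        x0 = np.full(k, np.log(0.25)) if start is None else np.log(np.clip(start, 1e-6, None))
        if k == 1:
            res = optimize.minimize_scalar(
                lambda d: objective(np.array([d])), bounds=(LOG_RATIO_MIN, LOG_RATIO_MAX), method="bounded",
                options={"xatol": 1e-6},
            )
            ls = np.array([res.x])
            success = res.success
        else:
            res = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                options={"xatol": 2e-3, "fatol": 2e-6, "maxiter": 400, "adaptive": True},
            )
            ls = res.x
            success = res.fun < np.inf
        ls = np.clip(ls, LOG_RATIO_MIN, LOG_RATIO_MAX)
        m2ll, aux = self._laplace_m2ll(ls, state)
        if aux is None or not np.isfinite(m2ll):
            raise ConvergenceError("Laplace optimization failed", trace)
        beta, u, cS, sigma2 = aux
        vcov_beta = cho_solve(cS, np.eye(self.X.shape[1]))
        return MixedFitResult(
            beta=beta,
            vcov_beta=vcov_beta,
            variances=sigma2,
            sigma2=float("nan"),
            loglik=-0.5 * m2ll,
            u=u,
            converged=bool(success),
            boundary=ls <= BOUNDARY_TOL,
            n_iter=len(trace),
            trace=trace,
        )
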