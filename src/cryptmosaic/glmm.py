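"""Poisson / negative-binomial random-intercept GLMMs.

The model for crypt j of mouse i with count response y_ij is

    y_ij | u_i ~ Poisson(mu_ij)   or   NB2(mu_ij, alpha)
    log mu_ij = x_ij' beta + offset_ij + u_i,      u_i ~ N(0, sigma_u^2)

with the NB2 variance mu + alpha*mu^2.  The marginal log-likelihood
integrates the mouse random intercept out numerically:

    l(beta, sigma_u, alpha) = sum_i log INT prod_j f(y_ij | u) phi(u; 0, sigma_u^2) du

Two integrators are provided.  The workhorse is adaptive Gauss–Hermite
quadrature (AGQ): per mouse, the integrand's mode is found by Newton
iteration (the integrand is log-concave for both families) and the
Hermite nodes are centred and scaled there, which keeps few-node rules
accurate even with 4 mice per group.  The second integrator is a dense
trapezoid grid over ±10 sigma — deliberately brute force, kept as an
independent oracle for the AGQ code path.

Fitting maximizes the AGQ log-likelihood over (beta, log sigma_u[, log
alpha]) from GLM starting values; standard errors come from the
numerical Hessian at the optimum, and rate-ratio inference is Wald.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

FAMILIES = ("poisson", "negbin")

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class GLMMSpec:
    """Model specification over a counts DataFrame.

    ``fixed_effects`` are numeric columns of the design (an intercept is
    always prepended).  ``exposure`` names a column whose log becomes
    the offset; alternatively ``offset`` names a column already on the
    log scale.  ``group`` is the random-intercept grouping factor.
    """

    family: str = "poisson"
    response: str = "y"
    fixed_effects: Sequence[str] = field(default_factory=list)
    exposure: str | None = None
    offset: str | None = None
    group: str = "mouse_id"
    quadrature_points: int = 20

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.exposure is not None and self.offset is not None:
            raise ValueError("give either exposure or offset, not both")
        if self.quadrature_points < 1:
            raise ValueError("quadrature_points must be positive")


@dataclass
class _Arrays:
    y: np.ndarray
    X: np.ndarray
    offset: np.ndarray
    groups: np.ndarray  # integer codes
    group_labels: list
    term_names: list[str]


def _build_arrays(data: pd.DataFrame, spec: GLMMSpec) -> _Arrays:
    spec.validate()
    for col in [spec.response, *spec.fixed_effects, spec.group]:
        if col not in data.columns:
            raise ValueError(f"column {col!r} not found in data")
    y = data[spec.response].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)) or not np.all(np.isfinite(y)):
        raise ValueError(f"response {spec.response!r} must be nonnegative integers")
    X = np.column_stack(
        [np.ones(len(data))]
        + [data[c].to_numpy(dtype=float) for c in spec.fixed_effects]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("design matrix is rank deficient; estimates are not unique", stacklevel=3)
    if spec.exposure is not None:
        expo = data[spec.exposure].to_numpy(dtype=float)
        if np.any(expo <= 0):
            raise ValueError(f"exposure {spec.exposure!r} must be positive")
        offset = np.log(expo)
    elif spec.offset is not None:
        offset = data[spec.offset].to_numpy(dtype=float)
    else:
        offset = np.zeros(len(data))
    if not np.all(np.isfinite(offset)):
        raise ValueError("offsets must be finite")
    codes, labels = pd.factorize(data[spec.group])
    return _Arrays(
        y=y,
        X=X,
        offset=offset,
        groups=codes,
        group_labels=list(labels),
        term_names=["Intercept", *spec.fixed_effects],
    )


def make_design(
    data: pd.DataFrame, by: str, reference: str
) -> tuple[pd.DataFrame, list[str]]:
    """Add 0/1 indicator columns contrasting each level of ``by`` with ``reference``.

    Returns the augmented frame and the new column names (one per
    non-reference level, in first-appearance order).
    """
    if by not in data.columns:
        raise ValueError(f"column {by!r} not found in data")
    levels = [l for l in pd.unique(data[by]) if l != reference]
    if reference not in set(data[by]):
        raise ValueError(f"reference level {reference!r} absent from column {by!r}")
    out = data.copy()
    names = []
    for lvl in levels:
        name = f"{by}[{lvl}]"
        out[name] = (out[by] == lvl).astype(float)
        names.append(name)
    return out, names


# ---------------------------------------------------------------------------
# family log-densities and derivatives w.r.t. the linear predictor eta
# ---------------------------------------------------------------------------

def _ll(family: str, y: np.ndarray, eta: np.ndarray, alpha: float | None) -> np.ndarray:
    mu = np.exp(eta)
    if family == "poisson":
        return y * eta - mu - gammaln(y + 1.0)
    r = 1.0 / alpha
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r)
        + y * eta
        - (y + r) * np.log(r + mu)
    )


def _d1(family: str, y: np.ndarray, eta: np.ndarray, alpha: float | None) -> np.ndarray:
    mu = np.exp(eta)
    if family == "poisson":
        return y - mu
    r = 1.0 / alpha
    return (y - mu) * r / (r + mu)


def _d2(family: str, y: np.ndarray, eta: np.ndarray, alpha: float | None) -> np.ndarray:
    mu = np.exp(eta)
    if family == "poisson":
        return -mu
    r = 1.0 / alpha
    return -r * mu * (r + y) / (r + mu) ** 2


def _conditional_modes(
    arr: _Arrays,
    eta0: np.ndarray,
    sigma: float,
    family: str,
    alpha: float | None,
    tol: float = 1e-10,
    max_iter: int = 100,
    u0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton iteration for the per-group mode of the joint log-density.

    Returns (mode u_hat, curvature −h'' at the mode) per group.  The
    objective is strictly concave in u, so undamped Newton with a step
    cap converges; ``u0`` warm-starts the iteration.
    """
    n_groups = len(arr.group_labels)
    u = np.zeros(n_groups) if u0 is None else u0.copy()
    inv_s2 = 1.0 / sigma**2

    def h_of(u_vec: np.ndarray) -> np.ndarray:
        eta = eta0 + u_vec[arr.groups]
        with np.errstate(over="ignore", invalid="ignore"):
            ll = _ll(family, arr.y, eta, alpha)
        return np.bincount(arr.groups, ll, n_groups) - 0.5 * u_vec**2 * inv_s2

    h_u = h_of(u)
    for _ in range(max_iter):
        eta = eta0 + u[arr.groups]
        g1 = np.bincount(arr.groups, _d1(family, arr.y, eta, alpha), n_groups) - u * inv_s2
        g2 = np.bincount(arr.groups, _d2(family, arr.y, eta, alpha), n_groups) - inv_s2
        step = np.clip(g1 / (-g2), -30.0, 30.0)
        # backtracking keeps the ascent monotone even where the likelihood is
        # quasi-linear and the curvature nearly vanishes (undamped Newton
        # oscillates there)
        for _ in range(60):
            h_new = h_of(u + step)
            bad = ~(h_new >= h_u - 1e-12)
            if not bad.any():
                break
            step = np.where(bad, 0.5 * step, step)
        u = u + step
        h_u = h_new
        if np.max(np.abs(step)) < tol:
            break
    eta = eta0 + u[arr.groups]
    curv = -(np.bincount(arr.groups, _d2(family, arr.y, eta, alpha), n_groups) - inv_s2)
    return u, curv


def _agq_loglik(
    arr: _Arrays,
    beta: np.ndarray,
    sigma: float,
    alpha: float | None,
    family: str,
    n_points: int,
    mode_cache: dict | None = None,
) -> float:
    eta0 = arr.X @ beta + arr.offset
    if sigma == 0.0:
        return float(np.sum(_ll(family, arr.y, eta0, alpha)))
    n_groups = len(arr.group_labels)
    u0 = mode_cache.get("u") if mode_cache is not None else None
    u_hat, curv = _conditional_modes(arr, eta0, sigma, family, alpha, u0=u0)
    if mode_cache is not None:
        mode_cache["u"] = u_hat
    tau = 1.0 / np.sqrt(curv)
    z, w = hermgauss(n_points)
    # evaluate all (observation, node) log-densities in one shot, then
    # accumulate per (group, node) with a single flattened bincount
    u_nodes = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * z[None, :]  # (G, Q)
    eta = eta0[:, None] + u_nodes[arr.groups, :]  # (n, Q)
    ll = _ll(family, arr.y[:, None], eta, alpha)
    idx = (arr.groups[:, None] * n_points + np.arange(n_points)[None, :]).ravel()
    h = np.bincount(idx, ll.ravel(), n_groups * n_points).reshape(n_groups, n_points)
    h += -0.5 * (u_nodes / sigma) ** 2 - np.log(sigma) - 0.5 * _LOG_2PI
    log_terms = np.log(w)[None, :] + (z**2)[None, :] + h
    li = logsumexp(log_terms, axis=1) + 0.5 * np.log(2.0) + np.log(tau)
    return float(np.sum(li))


def _grid_loglik(
    arr: _Arrays,
    beta: np.ndarray,
    sigma: float,
    alpha: float | None,
    family: str,
    n_points: int = 4001,
    half_width_sd: float = 10.0,
) -> float:
    """Brute-force trapezoid integration on a dense fixed grid (the oracle)."""
    eta0 = arr.X @ beta + arr.offset
    if sigma == 0.0:
        return float(np.sum(_ll(family, arr.y, eta0, alpha)))
    grid = np.linspace(-half_width_sd * sigma, half_width_sd * sigma, n_points)
    log_phi = -0.5 * (grid / sigma) ** 2 - np.log(sigma) - 0.5 * _LOG_2PI
    total = 0.0
    n_groups = len(arr.group_labels)
    for g in range(n_groups):
        idx = arr.groups == g
        yg = arr.y[idx]
        eg = eta0[idx]
        # (rows, grid) log-density matrix summed over rows
        ll = _ll(family, yg[:, None], eg[:, None] + grid[None, :], alpha).sum(axis=0)
        logf = ll + log_phi
        m = logf.max()
        total += m + np.log(np.trapezoid(np.exp(logf - m), grid))
    return float(total)


def marginal_loglik(
    data: pd.DataFrame,
    spec: GLMMSpec,
    beta: Sequence[float],
    sigma_u: float,
    alpha: float | None = None,
    method: str = "agq",
    n_points: int | None = None,
) -> float:
    """Marginal log-likelihood at the given parameter values.

    ``method`` is ``"agq"`` (adaptive Gauss–Hermite, default) or
    ``"grid_oracle"`` (dense trapezoid grid, the independent check).
    """
    if sigma_u < 0:
        raise ValueError("sigma_u must be nonnegative")
    if spec.family == "negbin":
        if alpha is None:
            raise ValueError("negbin family requires alpha")
        if alpha <= 0:
            raise ValueError("alpha must be positive for the negbin family")
    arr = _build_arrays(data, spec)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (arr.X.shape[1],):
        raise ValueError(f"beta must have {arr.X.shape[1]} elements (incl. intercept)")
    if method == "agq":
        return _agq_loglik(arr, beta, sigma_u, alpha, spec.family, n_points or spec.quadrature_points)
    if method in ("grid", "grid_oracle"):
        return _grid_loglik(arr, beta, sigma_u, alpha, spec.family, n_points or 4001)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_SIGMA_FLOOR = 1e-3  # below this the fit is reported as a boundary (sigma_u = 0)


@dataclass
class GLMMFit:
    """Maximum-likelihood fit of the random-intercept count GLMM."""

    family: str
    term_names: list[str]
    beta: np.ndarray
    se_beta: np.ndarray
    sigma_u: float
    alpha: float | None
    loglik: float
    converged: bool
    boundary_sigma: bool
    n_obs: int
    n_groups: int
    spec: GLMMSpec

    def term_index(self, term: str) -> int:
        try:
            return self.term_names.index(term)
        except ValueError:
            raise ValueError(
                f"unknown term {term!r}; available: {self.term_names}"
            ) from None

    def summary_frame(self) -> pd.DataFrame:
        rows = [wald_summary(self, t).as_dict() for t in self.term_names]
        df = pd.DataFrame(rows)
        df.insert(0, "response", self.spec.response)
        df["sigma_u"] = self.sigma_u
        df["alpha"] = self.alpha if self.alpha is not None else np.nan
        df["loglik"] = self.loglik
        df["converged"] = self.converged
        return df


def _glm_start(arr: _Arrays, family: str) -> tuple[np.ndarray, float | None]:
    """Poisson GLM starting values; moment estimate of alpha for NB."""
    import statsmodels.api as sm

    try:
        glm = sm.GLM(arr.y, arr.X, family=sm.families.Poisson(), offset=arr.offset)
        res = glm.fit()
        beta0 = np.asarray(res.params, dtype=float)
        mu = np.asarray(res.mu, dtype=float)
    except Exception:  # pragma: no cover - degenerate inputs
        beta0 = np.zeros(arr.X.shape[1])
        beta0[0] = np.log(max(arr.y.mean(), 0.1)) - arr.offset.mean()
        mu = np.exp(arr.X @ beta0 + arr.offset)
    alpha0 = None
    if family == "negbin":
        num = np.sum((arr.y - mu) ** 2 - mu)
        den = np.sum(mu**2)
        alpha0 = float(np.clip(num / den if den > 0 else 0.1, 1e-3, 5.0))
    return beta0, alpha0


def _numerical_hessian(fun, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    p = len(x0)
    h = rel_step * (1.0 + np.abs(x0))
    hess = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                f1 = fun(x0 + ei)
                f2 = fun(x0 - ei)
                f0 = fun(x0)
                hess[i, i] = (f1 - 2.0 * f0 + f2) / h[i] ** 2
            else:
                fpp = fun(x0 + ei + ej)
                fpm = fun(x0 + ei - ej)
                fmp = fun(x0 - ei + ej)
                fmm = fun(x0 - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return hess


def fit_glmm(data: pd.DataFrame, spec: GLMMSpec) -> GLMMFit:
    """Fit the random-intercept GLMM by maximizing the AGQ marginal likelihood.

    sigma_u (and alpha, for the NB family) are optimized on the log
    scale; a sigma_u estimate collapsing to the lower boundary is
    reported as 0 with ``boundary_sigma=True``.  ``converged`` honestly
    reflects the optimizer; a fit is returned either way.
    """
    arr = _build_arrays(data, spec)
    family = spec.family
    n_points = spec.quadrature_points
    p = arr.X.shape[1]
    beta0, alpha0 = _glm_start(arr, family)

    is_nb = family == "negbin"
    theta0 = np.concatenate([beta0, [np.log(0.3)], [np.log(alpha0)] if is_nb else []])

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, float, float | None]:
        beta = theta[:p]
        sigma = float(np.exp(theta[p]))
        alpha = float(np.exp(theta[p + 1])) if is_nb else None
        return beta, sigma, alpha

    mode_cache: dict = {}

    def negll(theta: np.ndarray) -> float:
        beta, sigma, alpha = unpack(theta)
        try:
            return -_agq_loglik(arr, beta, sigma, alpha, family, n_points, mode_cache)
        except (FloatingPointError, OverflowError):  # pragma: no cover
            return 1e12

    bounds = [(None, None)] * p + [(-8.0, 3.0)] + ([(-10.0, 3.0)] if is_nb else [])
    with np.errstate(over="ignore", invalid="ignore"):
        res = minimize(negll, theta0, method="L-BFGS-B", bounds=bounds)
    beta_hat, sigma_hat, alpha_hat = unpack(res.x)
    loglik = -float(res.fun)
    boundary = sigma_hat < _SIGMA_FLOOR
    if boundary:
        # report the likelihood at sigma_u = 0 so it is consistent with the
        # reported (boundary) variance
        loglik = _agq_loglik(arr, beta_hat, 0.0, alpha_hat, family, n_points)

    # numerical Hessian of -loglik; at a sigma boundary the sigma block is
    # degenerate, so fall back to the beta block alone
    se_beta = np.full(p, np.nan)
    try:
        with np.errstate(over="ignore", invalid="ignore"):
            hess = _numerical_hessian(negll, res.x)
            free = list(range(p)) if boundary else list(range(len(res.x)))
            sub = hess[np.ix_(free, free)]
            cov = np.linalg.inv(sub)
            diag = np.diag(cov)[:p]
            if np.all(diag > 0):
                se_beta = np.sqrt(diag)
            else:
                raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        try:
            hess_b = _numerical_hessian(lambda b: negll(np.concatenate([b, res.x[p:]])), beta_hat)
            with np.errstate(invalid="ignore"):
                # NaN where the information is singular (e.g. aliased terms)
                se_beta = np.sqrt(np.diag(np.linalg.pinv(hess_b)))
        except Exception:  # pragma: no cover
            pass

    return GLMMFit(
        family=family,
        term_names=arr.term_names,
        beta=beta_hat,
        se_beta=se_beta,
        sigma_u=0.0 if boundary else sigma_hat,
        alpha=alpha_hat,
        loglik=loglik,
        converged=bool(res.success),
        boundary_sigma=boundary,
        n_obs=len(arr.y),
        n_groups=len(arr.group_labels),
        spec=spec,
    )


@dataclass
class WaldSummary:
    term: str
    estimate: float
    se: float
    rate_ratio: float
    ci_low: float
    ci_high: float
    z: float
    p: float

    def as_dict(self) -> dict:
        return {
            "term": self.term,
            "estimate": self.estimate,
            "se": self.se,
            "rate_ratio": self.rate_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "z": self.z,
            "p": self.p,
        }


def wald_summary(fit: GLMMFit, term: str) -> WaldSummary:
    """Rate ratio, 95% Wald CI and two-sided normal p-value for one term.

    No multiple-testing adjustment is applied (raw p-values).
    """
    i = fit.term_index(term)
    b = float(fit.beta[i])
    se = float(fit.se_beta[i])
    z = b / se if se > 0 else np.inf * np.sign(b) if b != 0 else 0.0
    p = float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return WaldSummary(
        term=term,
        estimate=b,
        se=se,
        rate_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - 1.96 * se)),
        ci_high=float(np.exp(b + 1.96 * se)),
        z=float(z),
        p=min(p, 1.0),
    )
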