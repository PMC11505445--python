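"""Censored-normal statistics for right-censored Ct data.

qPCR non-detects are wells whose signal never crossed threshold before
the last cycle L (here Ct = 40): the underlying Ct exists but is only
known to exceed L.  All estimation here therefore maximises the classic
tobit likelihood

    ℓ(β, σ) = Σ_obs log φ((y_i − x_iᵀβ)/σ)/σ + Σ_cens log(1 − Φ((L_i − x_iᵀβ)/σ)),

with per-observation limits L_i (needed after per-sample reference
normalization).  Optimisation is in (β, log σ) with the analytic
gradient; Wald standard errors come from a finite-difference Hessian of
that gradient.  Fits are deterministic: initialisation is always the
moment estimate from the uncensored observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.weightstats import ttost_ind

_LOG_2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# likelihood machinery (shared by the one-sample fit and two-group tobit)
# ---------------------------------------------------------------------------

def _nll_and_grad(theta, X, y, cens, limits):
    """Negative censored-normal log-likelihood and gradient.

    theta = (β..., log σ); X is n×p; cens marks censored rows, for which
    y is ignored and ``limits`` supplies the censor point.
    """
    p = X.shape[1]
    beta = theta[:p]
    log_s = theta[p]
    s = np.exp(log_s)
    mu = X @ beta

    obs = ~cens
    z = (y[obs] - mu[obs]) / s
    nll = np.sum(0.5 * z**2 + log_s + 0.5 * _LOG_2PI)
    g_beta = -(X[obs].T @ z) / s
    g_logs = np.sum(1.0 - z**2)

    if cens.any():
        u = (limits[cens] - mu[cens]) / s
        log_sf = stats.norm.logsf(u)
        nll -= np.sum(log_sf)
        hazard = np.exp(stats.norm.logpdf(u) - log_sf)  # φ(u)/(1−Φ(u))
        g_beta += -(X[cens].T @ hazard) / s
        g_logs += -np.sum(hazard * u)

    grad = np.empty(p + 1)
    grad[:p] = g_beta
    grad[p] = g_logs
    return nll, grad


def _numerical_hessian(theta, X, y, cens, limits, eps=1e-5):
    """Central finite differences of the analytic gradient."""
    k = theta.size
    H = np.empty((k, k))
    for j in range(k):
        step = np.zeros(k)
        step[j] = eps * max(1.0, abs(theta[j]))
        _, g_plus = _nll_and_grad(theta + step, X, y, cens, limits)
        _, g_minus = _nll_and_grad(theta - step, X, y, cens, limits)
        H[:, j] = (g_plus - g_minus) / (2.0 * step[j])
    return 0.5 * (H + H.T)


def _maximize(X, y, cens, limits, theta0):
    res = optimize.minimize(
        _nll_and_grad,
        theta0,
        args=(X, y, cens, limits),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    return res


# ---------------------------------------------------------------------------
# one-sample censored-normal fit
# ---------------------------------------------------------------------------

@dataclass
class CensoredFit:
    """MLE of a normal distribution right-censored at a detection limit."""

    mu: float
    sigma: float
    n_obs: int
    n_cens: int
    loglik: float
    converged: bool


def fit_censored_normal(values, censored=None, limit: float = 40.0) -> CensoredFit:
    """Fit N(μ, σ²) to data right-censored at ``limit``.

    ``values`` holds the observed measurements; ``censored`` either a
    boolean mask aligned with ``values`` (censored entries' values are
    ignored) or None meaning nothing is censored.  With no censoring the
    optimum is the ordinary MLE (mean, 1/n standard deviation); the
    optimiser is initialised there and simply confirms it.
    """
    y = np.asarray(values, dtype=float)
    if censored is None:
        cens = np.zeros(y.shape, dtype=bool)
    else:
        cens = np.asarray(censored, dtype=bool)
    if not np.isfinite(limit):
        raise ValueError("detection limit must be finite")
    obs = y[~cens]
    if obs.size < 2:
        raise ValueError(
            f"need >= 2 uncensored values to identify (mu, sigma); got {obs.size}"
        )
    s0 = obs.std()  # MLE convention (1/n)
    if s0 <= 0:
        if cens.any():
            raise ValueError("degenerate fit: all uncensored values identical")
        return CensoredFit(
            mu=float(obs.mean()), sigma=0.0, n_obs=obs.size, n_cens=0,
            loglik=np.inf, converged=True,
        )

    X = np.ones((y.size, 1))
    limits = np.full(y.size, limit, dtype=float)
    theta0 = np.array([obs.mean(), np.log(s0)])
    res = _maximize(X, y, cens, limits, theta0)
    mu_hat = float(res.x[0])
    sigma_hat = float(np.exp(res.x[1]))
    if sigma_hat < 1e-8:
        raise ValueError("degenerate fit: sigma collapsed toward zero")
    return CensoredFit(
        mu=mu_hat,
        sigma=sigma_hat,
        n_obs=int(obs.size),
        n_cens=int(cens.sum()),
        loglik=float(-res.fun),
        converged=bool(res.success),
    )


def censored_loglik(mu, sigma, values, censored, limit) -> float:
    """Censored-normal log-likelihood at (mu, sigma); used for diagnostics."""
    y = np.asarray(values, dtype=float)
    cens = np.asarray(censored, dtype=bool)
    theta = np.array([mu, np.log(sigma)])
    nll, _ = _nll_and_grad(
        theta, np.ones((y.size, 1)), y, cens, np.full(y.size, float(limit))
    )
    return -nll


# ---------------------------------------------------------------------------
# truncated-normal sampling (for non-detect imputation)
# ---------------------------------------------------------------------------

def sample_truncated_normal(mu, sigma, lower, n, seed=None, rng=None):
    """Draw n values from N(mu, sigma²) conditioned on value ≥ lower.

    Uses the inverse-CDF sampler (scipy.stats.truncnorm), which stays
    accurate arbitrarily far into the upper tail — no rejection loops.
    ``lower = -inf`` recovers the untruncated normal.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    a = (lower - mu) / sigma if np.isfinite(lower) else -np.inf
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)


def truncated_normal_mean(mu, sigma, lower) -> float:
    """Closed-form mean of N(mu, sigma²) truncated to [lower, ∞)."""
    alpha = (lower - mu) / sigma
    return mu + sigma * np.exp(stats.norm.logpdf(alpha) - stats.norm.logsf(alpha))


# ---------------------------------------------------------------------------
# two-group tobit regression
# ---------------------------------------------------------------------------

@dataclass
class TobitResult:
    """Two-group censored regression y* = β0 + β1·g + ε, ε ~ N(0, σ²)."""

    beta0: float
    beta1: float
    sigma: float
    se_beta1: float
    p_value: float
    loglik: float
    converged: bool
    n_obs: int
    n_cens: int


def tobit_two_group(y, censored, group, limits) -> TobitResult:
    """Censored-regression MLE of a group effect with per-row censor limits.

    ``group`` is a 0/1 indicator (1 = case); ``censored`` marks rows
    observed only as exceeding ``limits``.  β1 is the case-minus-control
    mean difference on the response scale; its two-sided Wald p-value
    uses the normal reference distribution.  With no censoring the MLE
    coincides with OLS group means.
    """
    y = np.asarray(y, dtype=float)
    cens = np.asarray(censored, dtype=bool)
    g = np.asarray(group, dtype=float)
    limits = np.broadcast_to(np.asarray(limits, dtype=float), y.shape).copy()
    if set(np.unique(g)) - {0.0, 1.0}:
        raise ValueError("group indicator must be 0/1")
    for lev in (0.0, 1.0):
        if (~cens & (g == lev)).sum() < 2:
            raise ValueError(
                f"group {int(lev)} has < 2 uncensored observations; "
                "effect not identifiable"
            )

    X = np.column_stack([np.ones_like(g), g])
    obs = ~cens
    m0 = y[obs & (g == 0)].mean()
    m1 = y[obs & (g == 1)].mean()
    fitted = np.where(g[obs] == 1, m1, m0)
    s0 = max(np.sqrt(np.mean((y[obs] - fitted) ** 2)), 1e-3)
    inits = [
        np.array([m0, m1 - m0, np.log(s0)]),
        np.array([m0, 0.0, np.log(2.0 * s0)]),
        np.array([np.median(y[obs]), 0.0, np.log(s0)]),
    ]
    best = None
    for k, theta0 in enumerate(inits):
        res = _maximize(X, y, cens, limits, theta0)
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if k == 0 and res.success:
            break  # watchdog restarts only on trouble
    res = best

    theta = res.x
    H = _numerical_hessian(theta, X, y, cens, limits)
    try:
        cov = np.linalg.inv(H)
        se1 = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se1 = np.nan
    converged = bool(res.success) and np.isfinite(se1) and se1 > 0
    beta1 = float(theta[1])
    if converged:
        zstat = beta1 / se1
        p = float(2.0 * stats.norm.sf(abs(zstat)))
    else:
        p = np.nan
    return TobitResult(
        beta0=float(theta[0]),
        beta1=beta1,
        sigma=float(np.exp(theta[2])),
        se_beta1=se1,
        p_value=p,
        loglik=float(-res.fun),
        converged=converged,
        n_obs=int(obs.sum()),
        n_cens=int(cens.sum()),
    )


# ---------------------------------------------------------------------------
# TOST equivalence
# ---------------------------------------------------------------------------

@dataclass
class TostResult:
    """Two one-sided Welch t-tests of |mean(a) − mean(b)| < margin."""

    margin: float
    p_lower: float
    p_upper: float
    p_tost: float
    equivalent: bool


def tost_two_group(a_values, b_values, margin: float = 0.5, alpha: float = 0.05) -> TostResult:
    """Equivalence of two group means within ±margin (Welch TOST).

    p_tost = max of the two one-sided p-values; equivalence is declared
    when p_tost < alpha, i.e. the (1−2α) CI for the difference lies
    inside (−margin, margin).
    """
    if margin <= 0:
        raise ValueError("margin must be > 0")
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TostResult(margin, 0.0, 0.0, 0.0, True)
        raise ValueError("degenerate: zero variance in both groups, unequal means")
    p_tost, lower, upper = ttost_ind(a, b, -margin, margin, usevar="unequal")
    p_lower = float(lower[1])
    p_upper = float(upper[1])
    p_tost = float(max(p_lower, p_upper))
    return TostResult(
        margin=float(margin),
        p_lower=p_lower,
        p_upper=p_upper,
        p_tost=p_tost,
        equivalent=bool(p_tost < alpha),
    )
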