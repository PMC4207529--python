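"""AR(p) estimation by conditional and exact maximum likelihood.

The EIL process is modelled as a stationary autoregression

    y_t = u + a_1 y_{t-1} + ... + a_p y_{t-p} + eps_t,   eps_t ~ N(0, sigma^2)

with process mean mu = u / (1 - sum a_j).  Two likelihoods are supported:

* conditional — the prediction-error decomposition conditioning on the
  first p observations,
      l_c = -((n-p)/2) log(2 pi sigma^2)
            - (1/(2 sigma^2)) sum_{t=p+1..n} (y_t - u - sum_j a_j y_{t-j})^2;
* exact — l_c plus the log density of the initial block (y_1..y_p) under
  the stationary Gaussian marginal, whose autocovariances solve the
  Yule-Walker equations (for p = 1 this is y_1 ~ N(mu, sigma^2/(1-a_1^2))).

Conditional maximization has the closed-form solution of ordinary least
squares of y_t on (1, y_{t-1}, ..., y_{t-p}); exact maximization is
numerical, over a parameterization (intercept, atanh partial
autocorrelations, log sigma^2) in which stationarity holds by construction.
Orders are compared with AIC = -2 loglik + 2 rho, rho counting coefficients,
the intercept (when estimated) and sigma^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .eil import YearlySeries
from .errors import (
    ConvergenceError,
    DomainError,
    InsufficientDataError,
    NonStationaryError,
)

__all__ = [
    "ARModel",
    "OrderSelection",
    "check_stationarity",
    "ar_characteristic_roots",
    "pacf_to_ar",
    "ar_to_pacf",
    "stationary_autocovariances",
    "log_likelihood_conditional",
    "log_likelihood_exact",
    "fit_ar",
    "aic",
    "select_order",
    "ma_representation",
]

LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ARModel:
    """A fitted (or specified) stationary AR(p) model.

    ``coeffs`` are a_1..a_p, ``intercept`` is the constant u (so the process
    mean is u/(1 - sum a_j)), ``sigma2`` the innovation variance.  ``loglik``
    and ``aic`` are populated by the fitting routines; for hand-built models
    they may be NaN.
    """

    p: int
    coeffs: np.ndarray
    intercept: float
    sigma2: float
    loglik: float = math.nan
    loglik_kind: str = "unset"  # "conditional" | "exact" | "unset"
    n_params: int = 0
    aic: float = math.nan

    def __post_init__(self) -> None:
        coeffs = np.atleast_1d(np.asarray(self.coeffs, dtype=float))
        if len(coeffs) != self.p or self.p < 1:
            raise DomainError(f"expected {self.p} coefficient(s), got {len(coeffs)}")
        if not np.isfinite(self.sigma2) or self.sigma2 <= 0:
            raise DomainError(f"innovation variance sigma2 must be > 0, got {self.sigma2!r}")
        stationary, moduli = check_stationarity(coeffs)
        if not stationary:
            raise NonStationaryError(
                f"AR coefficients are non-stationary (min root modulus {moduli.min():.6g} <= 1)"
            )
        object.__setattr__(self, "coeffs", coeffs)

    @property
    def mean(self) -> float:
        """Stationary process mean mu = u / (1 - sum a_j)."""
        return self.intercept / (1.0 - self.coeffs.sum())

    @property
    def sigma(self) -> float:
        return math.sqrt(self.sigma2)


@dataclass(frozen=True)
class OrderSelection:
    """Result of AIC order comparison: the winning model plus the table."""

    best: ARModel
    models: tuple[ARModel, ...]
    table: "object"  # pandas.DataFrame (order, a_1.., intercept, sigma2, loglik, aic)


def ar_characteristic_roots(coeffs: np.ndarray) -> np.ndarray:
    """Roots of 1 - a_1 z - ... - a_p z^p.

    Computed as reciprocals of the roots of the monic reversed polynomial
    z^p - a_1 z^{p-1} - ... - a_p, which keeps the companion matrix
    well-conditioned for arbitrarily small coefficients; zero reciprocal
    roots (trailing zero coefficients) map to roots at infinity.
    """
    coeffs = np.atleast_1d(np.asarray(coeffs, dtype=float))
    inv = np.roots(np.concatenate(([1.0], -coeffs)))
    roots = np.full(len(inv), np.inf, dtype=complex)
    nz = inv != 0
    with np.errstate(over="ignore"):
        roots[nz] = 1.0 / inv[nz]
    return roots


def check_stationarity(coeffs: np.ndarray) -> tuple[bool, np.ndarray]:
    """True iff every characteristic root lies strictly outside the unit circle.

    Returns (stationary, root moduli); a zero-coefficient model has no roots
    and is trivially stationary.
    """
    roots = ar_characteristic_roots(coeffs)
    moduli = np.abs(roots)
    if len(moduli) == 0:
        return True, np.array([np.inf])
    return bool(moduli.min() > 1.0), moduli


def pacf_to_ar(partials: np.ndarray) -> np.ndarray:
    """Map partial autocorrelations k_1..k_p to AR coefficients (Durbin-Levinson).

    Any vector with all |k_i| < 1 maps to a stationary coefficient vector,
    which makes this the natural unconstrained-optimization parameterization.
    """
    partials = np.atleast_1d(np.asarray(partials, dtype=float))
    a = np.array([partials[0]])
    for m in range(2, len(partials) + 1):
        km = partials[m - 1]
        new = np.empty(m)
        new[: m - 1] = a - km * a[::-1]
        new[m - 1] = km
        a = new
    return a


def ar_to_pacf(coeffs: np.ndarray) -> np.ndarray:
    """Inverse of :func:`pacf_to_ar` (reverse Levinson recursion)."""
    a = np.atleast_1d(np.asarray(coeffs, dtype=float)).copy()
    p = len(a)
    partials = np.empty(p)
    for m in range(p, 1, -1):
        km = a[m - 1]
        partials[m - 1] = km
        if abs(km) >= 1.0:
            raise NonStationaryError("reflection coefficient |k_m| >= 1; model non-stationary")
        a = (a[: m - 1] + km * a[: m - 1][::-1]) / (1.0 - km * km)
    partials[0] = a[0]
    return partials


def stationary_autocovariances(coeffs: np.ndarray, sigma2: float, max_lag: int) -> np.ndarray:
    """Stationary autocovariances gamma_0..gamma_max_lag of an AR(p) process.

    gamma_0..gamma_p solve the linear Yule-Walker system
    gamma_0 - sum_j a_j gamma_j = sigma^2, gamma_k - sum_j a_j gamma_|k-j| = 0;
    higher lags follow the recursion gamma_k = sum_j a_j gamma_{k-j}.
    """
    a = np.atleast_1d(np.asarray(coeffs, dtype=float))
    p = len(a)
    stationary, _ = check_stationarity(a)
    if not stationary:
        raise NonStationaryError("stationary autocovariances do not exist")
    m = max(p, max_lag)
    A = np.eye(p + 1)
    for k in range(p + 1):
        for j in range(1, p + 1):
            A[k, abs(k - j)] -= a[j - 1]
    b = np.zeros(p + 1)
    b[0] = sigma2
    gam = np.linalg.solve(A, b)
    out = np.empty(m + 1)
    out[: p + 1] = gam
    for k in range(p + 1, m + 1):
        out[k] = float(a @ out[k - 1 : k - 1 - p : -1] if p > 1 else a[0] * out[k - 1])
    return out[: max_lag + 1]


def _prediction_errors(coeffs: np.ndarray, intercept: float, y: np.ndarray) -> np.ndarray:
    """One-step errors y_t - u - sum_j a_j y_{t-j} for t = p+1..n."""
    p = len(coeffs)
    pred = np.full(len(y) - p, intercept)
    for j in range(1, p + 1):
        pred += coeffs[j - 1] * y[p - j : len(y) - j]
    return y[p:] - pred


def log_likelihood_conditional(model: ARModel, series: YearlySeries) -> float:
    """Gaussian log-likelihood conditioning on the first p observations."""
    y = series.values
    n = len(y)
    if n <= model.p:
        raise InsufficientDataError(f"need n > p = {model.p}, got n = {n}")
    e = _prediction_errors(model.coeffs, model.intercept, y)
    return float(
        -0.5 * (n - model.p) * (LOG_2PI + math.log(model.sigma2))
        - 0.5 * (e @ e) / model.sigma2
    )


def log_likelihood_exact(model: ARModel, series: YearlySeries) -> float:
    """Exact Gaussian log-likelihood of a stationary AR(p).

    Conditional log-likelihood plus the log density of (y_1..y_p) under the
    stationary marginal: mean mu in every coordinate, covariance from the
    Yule-Walker autocovariances.  For p = 1 this initial term is the
    N(mu, sigma^2/(1-a_1^2)) density of y_1.
    """
    cond = log_likelihood_conditional(model, series)
    p = model.p
    gamma = stationary_autocovariances(model.coeffs, model.sigma2, p - 1 if p > 1 else 0)
    y0 = series.values[:p] - model.mean
    if p == 1:
        var0 = gamma[0]
        init = -0.5 * (LOG_2PI + math.log(var0) + y0[0] ** 2 / var0)
    else:
        cov = np.empty((p, p))
        for i in range(p):
            for j in range(p):
                cov[i, j] = gamma[abs(i - j)]
        init = stats.multivariate_normal.logpdf(y0, mean=np.zeros(p), cov=cov)
    return float(cond + init)


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion, -2*loglik + 2*n_params."""
    if n_params < 0:
        raise DomainError(f"n_params must be >= 0, got {n_params}")
    return -2.0 * loglik + 2.0 * n_params


def _conditional_ols(y: np.ndarray, p: int, zero_mean: bool):
    """Closed-form conditional MLE: OLS of y_t on (1, y_{t-1..t-p})."""
    n = len(y)
    rows = n - p
    cols = []
    if not zero_mean:
        cols.append(np.ones(rows))
    for j in range(1, p + 1):
        cols.append(y[p - j : n - j])
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y[p:], rcond=None)
    resid = y[p:] - X @ beta
    sigma2 = float(resid @ resid) / rows
    if zero_mean:
        return 0.0, beta, sigma2
    return float(beta[0]), beta[1:], sigma2


def _finish(model_args, series, kind, zero_mean) -> ARModel:
    intercept, coeffs, sigma2 = model_args
    p = len(coeffs)
    base = ARModel(p=p, coeffs=coeffs, intercept=intercept, sigma2=sigma2)
    ll = (
        log_likelihood_exact(base, series)
        if kind == "exact"
        else log_likelihood_conditional(base, series)
    )
    rho = p + 1 + (0 if zero_mean else 1)  # coefficients + sigma2 (+ intercept)
    return ARModel(
        p=p,
        coeffs=coeffs,
        intercept=intercept,
        sigma2=sigma2,
        loglik=ll,
        loglik_kind=kind,
        n_params=rho,
        aic=aic(ll, rho),
    )


def _optimize_likelihood(
    y: np.ndarray, series: YearlySeries, p: int, kind: str, zero_mean: bool, x0
) -> tuple[float, np.ndarray, float]:
    """Maximize the requested likelihood over a stationarity-preserving space.

    Parameter vector: [intercept (unless zero-mean), atanh(k_1..k_p),
    log sigma^2]; the tanh/Durbin-Levinson map keeps every iterate strictly
    stationary, so the exact likelihood is always defined.
    """

    def unpack(x):
        off = 0 if zero_mean else 1
        intercept = 0.0 if zero_mean else x[0]
        coeffs = pacf_to_ar(np.tanh(x[off : off + p]))
        sigma2 = math.exp(x[off + p])
        return intercept, coeffs, sigma2

    def negloglik(x):
        intercept, coeffs, sigma2 = unpack(x)
        try:
            m = ARModel(p=p, coeffs=coeffs, intercept=intercept, sigma2=sigma2)
        except DomainError:
            return 1e12
        ll = (
            log_likelihood_exact(m, series)
            if kind == "exact"
            else log_likelihood_conditional(m, series)
        )
        if not np.isfinite(ll):
            return 1e12
        return -ll

    res = optimize.minimize(
        negloglik,
        x0,
        method="L-BFGS-B",
        options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
    )
    best = res
    # polish / fall back with a simplex pass if the quasi-Newton stalls
    if not res.success or not np.isfinite(res.fun):
        res2 = optimize.minimize(
            negloglik,
            res.x if np.all(np.isfinite(res.x)) else x0,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000},
        )
        if res2.fun <= res.fun or not np.isfinite(res.fun):
            best = res2
        if not best.success and not np.isfinite(best.fun):
            raise ConvergenceError(
                f"likelihood optimization failed for AR({p}) [{kind}]: {best.message}",
                last_objective=float(best.fun),
                last_params=np.asarray(best.x),
            )
    return unpack(best.x)


def fit_ar(
    series: YearlySeries,
    p: int,
    method: str = "exact",
    zero_mean: bool = False,
) -> ARModel:
    """Fit a stationary AR(p) by maximum likelihood.

    ``method='conditional'`` uses the closed-form OLS solution of the
    prediction-error decomposition (falling back to constrained optimization
    only if OLS lands outside the stationary region); ``method='exact'``
    maximizes the exact likelihood numerically, initialized from the
    conditional fit.  The returned model carries the maximized log-likelihood
    and its AIC.
    """
    if method not in ("conditional", "exact"):
        raise DomainError(f"method must be 'conditional' or 'exact', got {method!r}")
    if p < 1:
        raise DomainError(f"order p must be >= 1, got {p}")
    y = series.values
    n = len(y)
    if n < p + 3:
        raise InsufficientDataError(
            f"need n >= p + 3 = {p + 3} observations to fit AR({p}), got {n}"
        )
    if np.ptp(y) == 0.0:
        raise DomainError("cannot fit an AR model to a constant series (zero variance)")

    intercept0, coeffs0, sigma20 = _conditional_ols(y, p, zero_mean)
    ols_stationary, _ = check_stationarity(coeffs0)

    if method == "conditional" and ols_stationary:
        if sigma20 <= 0:
            raise DomainError("conditional fit degenerate: zero residual variance")
        return _finish((intercept0, coeffs0, sigma20), series, "conditional", zero_mean)

    # starting point in the unconstrained space
    if ols_stationary:
        partials0 = np.clip(ar_to_pacf(coeffs0), -0.98, 0.98)
    else:
        partials0 = np.full(p, 0.1)
    x0 = []
    if not zero_mean:
        x0.append(intercept0)
    x0.extend(np.arctanh(partials0))
    x0.append(math.log(max(sigma20, 1e-12)))
    args = _optimize_likelihood(y, series, p, method, zero_mean, np.asarray(x0))
    return _finish(args, series, method, zero_mean)


def select_order(
    series: YearlySeries,
    max_p: int = 3,
    method: str = "exact",
    zero_mean: bool = False,
) -> OrderSelection:
    """Fit AR(1)..AR(max_p) and pick the minimum-AIC model.

    All candidates use the same likelihood kind so their AICs are
    comparable; ties (and exact AIC equality) resolve toward the smaller
    order.  Returns the winner plus the full comparison table.
    """
    import pandas as pd

    if max_p < 1:
        raise DomainError(f"max_p must be >= 1, got {max_p}")
    if series.n < max_p + 3:
        raise InsufficientDataError(
            f"need n >= max_p + 3 = {max_p + 3} observations, got {series.n}"
        )
    models = []
    for p in range(1, max_p + 1):
        try:
            models.append(fit_ar(series, p, method=method, zero_mean=zero_mean))
        except (DomainError, ConvergenceError) as err:
            raise type(err)(f"fit failed at order p={p}: {err}") from err
    best = models[0]
    for m in models[1:]:
        if m.aic < best.aic:
            best = m
    rows = []
    for m in models:
        row = {"order": m.p}
        for j in range(1, max_p + 1):
            row[f"a_{j}"] = m.coeffs[j - 1] if j <= m.p else math.nan
        row.update(
            intercept=m.intercept,
            sigma2=m.sigma2,
            loglik=m.loglik,
            aic=m.aic,
        )
        rows.append(row)
    return OrderSelection(best=best, models=tuple(models), table=pd.DataFrame(rows))


def ma_representation(model: ARModel, n_terms: int) -> np.ndarray:
    """MA(infinity) weights theta_0..theta_{n_terms-1} of a stationary AR(p).

    theta_0 = 1 and theta_j = sum_{k=1..min(j,p)} a_k theta_{j-k}; for a
    stationary model the weights are square-summable and sigma^2 times their
    cumulative squared sums give the h-step forecast-error variances.
    """
    if n_terms < 1:
        raise DomainError(f"n_terms must be >= 1, got {n_terms}")
    a = model.coeffs
    p = model.p
    theta = np.zeros(n_terms)
    theta[0] = 1.0
    for j in range(1, n_terms):
        kmax = min(j, p)
        theta[j] = sum(a[k - 1] * theta[j - k] for k in range(1, kmax + 1))
    return theta
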