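"""h-step forecasting with Gaussian prediction intervals, residual checks.

Point forecasts iterate the AR recursion with observed values where
available and previous forecasts otherwise; the h-step forecast-error
standard deviation is sigma * sqrt(sum_{j<h} theta_j^2) with theta_j the
MA(infinity) weights, so intervals widen toward the stationary process SD
and the point forecast reverts geometrically to the process mean.
Intervals are plug-in: parameter-estimation uncertainty is ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ar import ARModel, fit_ar, ma_representation
from .eil import YearlySeries
from .errors import DomainError, InsufficientDataError

__all__ = [
    "Forecast",
    "ResidualReport",
    "Backtest",
    "forecast",
    "residual_diagnostics",
    "backtest_one_step",
]


@dataclass(frozen=True)
class Forecast:
    """Point forecasts with symmetric Gaussian prediction intervals."""

    years: np.ndarray
    point: np.ndarray
    pi_lower: np.ndarray
    pi_upper: np.ndarray
    forecast_sd: np.ndarray
    level: float
    horizon: int


@dataclass(frozen=True)
class ResidualReport:
    """One-step in-sample residuals and a normality assessment.

    ``normality`` is the Shapiro-Wilk (statistic, p-value) on the residuals
    — chosen as a single omnibus test with good power at the short series
    lengths typical here.  ``qq_points`` pairs theoretical quantiles of the
    fitted N(0, sigma^2) with the ordered residuals.
    """

    residuals: np.ndarray
    fitted: np.ndarray
    normality: tuple[float, float]
    qq_points: np.ndarray  # shape (n-p, 2): theoretical, empirical


@dataclass(frozen=True)
class Backtest:
    """Held-out one-step predictions: (year, observed, predicted) and MAE."""

    years: np.ndarray
    observed: np.ndarray
    predicted: np.ndarray
    mae: float  # NaN when the holdout is empty
    model: ARModel

    @property
    def empty(self) -> bool:
        return len(self.years) == 0


def forecast(
    model: ARModel, series: YearlySeries, horizon: int = 5, level: float = 0.95
) -> Forecast:
    """Forecast the next ``horizon`` years from the end of ``series``.

    For AR(1) the point forecast is mu + a^h (y_n - mu) and the h-step
    forecast variance is sigma^2 (1 - a^{2h}) / (1 - a^2), both recovered
    here through the general recursion and psi-weight summation.
    """
    if horizon < 1:
        raise DomainError(f"forecast horizon must be >= 1, got {horizon}")
    if not 0 < level < 1:
        raise DomainError(f"coverage level must lie in (0, 1), got {level!r}")
    if series.n < model.p:
        raise InsufficientDataError(
            f"series shorter than model order (n={series.n} < p={model.p})"
        )
    a = model.coeffs
    history = list(series.values)
    point = np.empty(horizon)
    for h in range(horizon):
        point[h] = model.intercept + sum(
            a[j - 1] * history[len(history) - j] for j in range(1, model.p + 1)
        )
        history.append(point[h])
    theta = ma_representation(model, horizon)
    sd = model.sigma * np.sqrt(np.cumsum(theta**2))
    z = stats.norm.ppf(0.5 + level / 2.0)
    years = np.arange(series.end_year + 1, series.end_year + 1 + horizon)
    return Forecast(
        years=years,
        point=point,
        pi_lower=point - z * sd,
        pi_upper=point + z * sd,
        forecast_sd=sd,
        level=level,
        horizon=horizon,
    )


def residual_diagnostics(model: ARModel, series: YearlySeries) -> ResidualReport:
    """One-step in-sample residuals of ``model`` on ``series``.

    Residuals are y_t - (u + sum_j a_j y_{t-j}) for t = p+1..n; the first p
    observations are consumed by conditioning.
    """
    y = series.values
    n = len(y)
    p = model.p
    if n <= p:
        raise InsufficientDataError(f"need n > p = {p}, got n = {n}")
    pred = np.full(n - p, model.intercept)
    for j in range(1, p + 1):
        pred += model.coeffs[j - 1] * y[p - j : n - j]
    resid = y[p:] - pred
    if len(resid) >= 3:
        stat, pval = stats.shapiro(resid)
    else:
        stat, pval = (math.nan, math.nan)  # normality is unassessable
    m = len(resid)
    # Blom plotting positions against the fitted innovation distribution
    probs = (np.arange(1, m + 1) - 0.375) / (m + 0.25)
    theoretical = stats.norm.ppf(probs, loc=0.0, scale=model.sigma)
    qq = np.column_stack([theoretical, np.sort(resid)])
    return ResidualReport(
        residuals=resid,
        fitted=pred,
        normality=(float(stat), float(pval)),
        qq_points=qq,
    )


def backtest_one_step(
    series: YearlySeries,
    p: int,
    holdout: int,
    method: str = "exact",
    zero_mean: bool = False,
) -> Backtest:
    """Fit on the first n-holdout years; predict each held-out year one step ahead.

    Predictions use the frozen training-window fit with the *observed*
    lagged values, mimicking how a yearly threshold forecast would be
    checked as new observations arrive.  MAE is NaN for an empty holdout.
    """
    if holdout < 0:
        raise DomainError(f"holdout must be >= 0, got {holdout}")
    n = series.n
    if n - holdout < p + 3:
        raise InsufficientDataError(
            f"training window of {n - holdout} years cannot support AR({p}) "
            f"(need >= {p + 3})"
        )
    train = YearlySeries(series.years[: n - holdout], series.values[: n - holdout])
    model = fit_ar(train, p, method=method, zero_mean=zero_mean)
    if holdout == 0:
        return Backtest(
            years=np.array([], dtype=int),
            observed=np.array([]),
            predicted=np.array([]),
            mae=math.nan,
            model=model,
        )
    y = series.values
    idx = np.arange(n - holdout, n)
    pred = np.full(holdout, model.intercept)
    for j in range(1, p + 1):
        pred += model.coeffs[j - 1] * y[idx - j]
    obs = y[idx]
    return Backtest(
        years=series.years[idx],
        observed=obs,
        predicted=pred,
        mae=float(np.mean(np.abs(obs - pred))),
        model=model,
    )
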