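"""Pre-modelling diagnostics for a yearly series.

Two checks precede the AR modelling of an EIL series: an individuals &
moving-range (I-MR) statistical-process-control chart, which verifies that
the process is in control (no special-cause outliers) and estimates the
process sigma from the mean moving range; and the sample autocorrelation /
partial autocorrelation functions, which establish short memory and suggest
the AR order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .eil import YearlySeries
from .errors import DomainError, InsufficientDataError

__all__ = [
    "D2",
    "D4",
    "ControlChartResult",
    "CorrelogramResult",
    "imr_chart",
    "sample_acf",
    "acf",
    "pacf",
    "correlogram",
    "durbin_levinson",
]

# SPC unbiasing constants for a moving range of span 2: E[range of 2 iid
# N(0,1)] = d2, and D4 bounds the moving-range chart itself.
D2 = 1.128
D4 = 3.267


@dataclass(frozen=True)
class ControlChartResult:
    """Individuals & moving-range chart summary.

    sigma_hat is the mean moving range divided by d2; control limits sit at
    center ± multiplier*sigma_hat (multiplier 3 by default).  ``degenerate``
    flags a constant series, whose limits have zero width.
    """

    center: float
    sigma_hat: float
    ucl: float
    lcl: float
    moving_ranges: np.ndarray
    mr_center: float
    mr_ucl: float
    outliers: np.ndarray
    multiplier: float
    degenerate: bool


@dataclass(frozen=True)
class CorrelogramResult:
    """Sample ACF and PACF at lags 1..max_lag with white-noise bands.

    ci_halfwidth is the constant z_{1-alpha/2}/sqrt(n) half-width per lag
    (the flat band drawn on standard correlograms); lag 0, where the ACF is
    identically 1, is not stored.
    """

    lags: np.ndarray
    acf: np.ndarray
    pacf: np.ndarray
    ci_halfwidth: np.ndarray
    n: int


def imr_chart(series: YearlySeries, multiplier: float = 3.0) -> ControlChartResult:
    """Individuals & moving-range control chart of a yearly series.

    The moving range is the lag-1 absolute difference |y_t - y_{t-1}|
    (span 2, because consecutive values have the greatest chance of being
    alike); process sigma is estimated as mean(MR)/d2.  Points beyond
    center ± multiplier*sigma_hat are flagged as outliers by index.
    """
    y = series.values
    n = len(y)
    if n < 3:
        raise InsufficientDataError(f"I-MR chart needs at least 3 observations, got {n}")
    if multiplier <= 0:
        raise DomainError(f"control-limit multiplier must be > 0, got {multiplier!r}")
    mr = np.abs(np.diff(y))
    mr_center = float(np.mean(mr))
    sigma_hat = mr_center / D2
    center = float(np.mean(y))
    ucl = center + multiplier * sigma_hat
    lcl = center - multiplier * sigma_hat
    outliers = np.flatnonzero((y > ucl) | (y < lcl))
    return ControlChartResult(
        center=center,
        sigma_hat=sigma_hat,
        ucl=ucl,
        lcl=lcl,
        moving_ranges=mr,
        mr_center=mr_center,
        mr_ucl=D4 * mr_center,
        outliers=outliers,
        multiplier=multiplier,
        degenerate=(sigma_hat == 0.0),
    )


def sample_acf(values: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelations r_0..r_max_lag.

    r_k = sum_t (y_t - ybar)(y_{t+k} - ybar) / sum_t (y_t - ybar)^2, the
    standard estimator with the full-series sum of squares in the
    denominator.  This choice keeps the sequence positive semidefinite,
    which the Durbin-Levinson recursion relies on.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if not 0 < max_lag < n:
        raise DomainError(f"max_lag must satisfy 0 < max_lag < n={n}, got {max_lag}")
    dev = y - y.mean()
    denom = float(dev @ dev)
    if denom == 0.0:
        raise DomainError("autocorrelation is undefined for a zero-variance series")
    r = np.empty(max_lag + 1)
    r[0] = 1.0
    for k in range(1, max_lag + 1):
        r[k] = float(dev[:-k] @ dev[k:]) / denom
    return r


def durbin_levinson(rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Durbin-Levinson recursion on autocorrelations rho_1..rho_m.

    Returns (pacf, phi) where pacf[k-1] is the lag-k partial autocorrelation
    and phi holds the order-m Yule-Walker coefficients phi_{m,1..m}.
    """
    rho = np.asarray(rho, dtype=float)
    m = len(rho)
    pacf = np.empty(m)
    phi = np.array([rho[0]])
    pacf[0] = rho[0]
    for k in range(2, m + 1):
        prev = phi
        # rho_k - sum_j phi_{k-1,j} rho_{k-j}
        num = rho[k - 1] - sum(prev[j] * rho[k - 2 - j] for j in range(k - 1))
        den = 1.0 - sum(prev[j] * rho[j] for j in range(k - 1))
        kk = num / den
        phi = np.empty(k)
        phi[: k - 1] = prev - kk * prev[::-1]
        phi[k - 1] = kk
        pacf[k - 1] = kk
    return pacf, phi


def correlogram(series: YearlySeries, max_lag: int, alpha: float = 0.05) -> CorrelogramResult:
    """ACF and PACF at lags 1..max_lag with (1-alpha) white-noise bands.

    PACF is computed from the sample ACF by the Durbin-Levinson recursion,
    so pacf_1 == acf_1 exactly and pacf_k equals the last coefficient of the
    order-k Yule-Walker fit.
    """
    n = series.n
    r = sample_acf(series.values, max_lag)
    pacf_vals, _ = durbin_levinson(r[1:])
    z = stats.norm.ppf(1 - alpha / 2)
    return CorrelogramResult(
        lags=np.arange(1, max_lag + 1),
        acf=r[1:].copy(),
        pacf=pacf_vals,
        ci_halfwidth=np.full(max_lag, z / np.sqrt(n)),
        n=n,
    )


def acf(series: YearlySeries, max_lag: int, alpha: float = 0.05) -> CorrelogramResult:
    """Sample autocorrelation function; see :func:`correlogram`."""
    return correlogram(series, max_lag, alpha)


def pacf(series: YearlySeries, max_lag: int, alpha: float = 0.05) -> CorrelogramResult:
    """Sample partial autocorrelation function; see :func:`correlogram`."""
    return correlogram(series, max_lag, alpha)
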