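import numpy as np
import pytest
from scipy import linalg, stats

from eilcast import YearlySeries, pacf_to_ar


def make_series(values, start_year=2000, **kw):
    values = np.asarray(values, dtype=float)
    years = np.arange(start_year, start_year + len(values))
    return YearlySeries(years=years, values=values, **kw)


def mvn_exact_loglik_oracle(coeffs, intercept, sigma2, values):
    """Joint stationary Gaussian log-density of the whole series.

    Independent route: autocovariances from statsmodels' ARMA machinery,
    density from scipy's multivariate normal on the full n x n Toeplitz
    covariance — no prediction-error decomposition anywhere.
    """
    from statsmodels.tsa.arima_process import arma_acovf

    coeffs = np.atleast_1d(coeffs)
    y = np.asarray(values, dtype=float)
    n = len(y)
    gamma = arma_acovf(np.r_[1.0, -coeffs], [1.0], nobs=n) * sigma2
    mu = intercept / (1.0 - coeffs.sum())
    return float(
        stats.multivariate_normal.logpdf(y, mean=np.full(n, mu), cov=linalg.toeplitz(gamma))
    )


def random_stationary_coeffs(rng, p, max_pacf=0.85):
    """Stationary AR coefficients via uniform partial autocorrelations."""
    return pacf_to_ar(rng.uniform(-max_pacf, max_pacf, size=p))


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
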