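"""Synthetic yearly series: AR(p) simulation and a case-study-like fixture.

The real driver of the modelled EIL process — a short yearly record of
commodity prices for an industrial peach cultivation — is not publicly
deposited, so this module generates series with the same statistical
character: short (n ~ 15), strictly positive, short-memory autocorrelation
that has decayed by lag 3, an approximately normal marginal, and an EIL
level in the low single digits (pest specimens per sampling unit).

Prices are simulated as AR(1) in log scale, which guarantees positivity and
yields mild right skew, a standard choice for commodity-price fixtures;
the EIL series then follows deterministically through EIL = C/(V I D K)
with the non-price variables held constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ar import check_stationarity
from .eil import YearlySeries, eil_series_from_prices
from .errors import DomainError, NonStationaryError

__all__ = [
    "SimulationConfig",
    "CASE_STUDY_CONSTANTS",
    "CASE_STUDY_PRICE_PROCESS",
    "simulate_ar",
    "simulate_case_study",
]

#: Fixed non-price EIL variables of the synthetic case study.  Chosen once
#: (cost C in currency/area, injury I per pest, damage D in yield loss per
#: injury, efficacy K) so that at the mean simulated price (~600
#: currency/yield unit) the EIL sits near 2.35 pests per sampling unit —
#: the magnitude a low-single-digit larvae-per-fruit threshold implies.
CASE_STUDY_CONSTANTS = {"C": 113.0, "I": 2.5, "D": 0.04, "K": 0.8}

#: AR(1) for log price: mean log-price log(600), lag-1 coefficient 0.6
#: (short memory, gone by lag 3), innovation SD 0.08 giving a ~10%
#: stationary coefficient of variation — a realistic yearly price swing.
CASE_STUDY_PRICE_PROCESS = {"a1": 0.6, "log_mean": float(np.log(600.0)), "innovation_sd": 0.08}


@dataclass(frozen=True)
class SimulationConfig:
    """True parameters and bookkeeping for one AR(p) simulation."""

    coeffs: np.ndarray
    intercept: float
    sigma2: float
    n: int
    seed: int
    burn_in: int = 200
    start_year: int = 1996
    p: int = field(init=False)

    def __post_init__(self) -> None:
        coeffs = np.atleast_1d(np.asarray(self.coeffs, dtype=float))
        object.__setattr__(self, "coeffs", coeffs)
        object.__setattr__(self, "p", len(coeffs))
        stationary, moduli = check_stationarity(coeffs)
        if not stationary:
            raise NonStationaryError(
                f"simulation coefficients are non-stationary (min root modulus "
                f"{moduli.min():.6g} <= 1)"
            )
        if self.n < 2:
            raise DomainError(f"series length n must be >= 2, got {self.n}")
        if self.burn_in < 0:
            raise DomainError(f"burn_in must be >= 0, got {self.burn_in}")
        if not np.isfinite(self.sigma2) or self.sigma2 < 0:
            raise DomainError(f"sigma2 must be >= 0, got {self.sigma2!r}")


def simulate_ar(config: SimulationConfig) -> YearlySeries:
    """Simulate y_t = u + sum_j a_j y_{t-j} + eps_t, eps_t ~ N(0, sigma^2).

    The recursion starts at the process mean, runs ``burn_in`` warm-up steps
    that are discarded, and labels the retained ``n`` values from
    ``start_year``.  Identical configs produce bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    a = config.coeffs
    p = config.p
    mu = config.intercept / (1.0 - a.sum())
    total = config.burn_in + config.n
    eps = rng.normal(0.0, np.sqrt(config.sigma2), size=total)
    y = np.empty(p + total)
    y[:p] = mu
    for t in range(total):
        acc = config.intercept
        for j in range(1, p + 1):
            acc += a[j - 1] * y[p + t - j]
        y[p + t] = acc + eps[t]
    values = y[p + config.burn_in :]
    years = np.arange(config.start_year, config.start_year + config.n)
    return YearlySeries(years=years, values=values)


def simulate_case_study(
    seed: int, n: int = 15, start_year: int = 1996
) -> tuple[YearlySeries, YearlySeries]:
    """Generate a case-study-like (prices, EILs) pair of yearly series.

    Log price follows a stationary AR(1) around log(600); the EIL series is
    the deterministic transform C/(V I D K) of the price series with the
    constants in :data:`CASE_STUDY_CONSTANTS`.  Both series share the years
    ``start_year .. start_year + n - 1`` and are strictly positive.
    """
    if n < 5:
        raise DomainError(f"case-study length n must be >= 5, got {n}")
    proc = CASE_STUDY_PRICE_PROCESS
    a1 = proc["a1"]
    cfg = SimulationConfig(
        coeffs=np.array([a1]),
        intercept=proc["log_mean"] * (1.0 - a1),
        sigma2=proc["innovation_sd"] ** 2,
        n=n,
        seed=seed,
        start_year=start_year,
    )
    log_prices = simulate_ar(cfg)
    prices = YearlySeries(
        years=log_prices.years, values=np.exp(log_prices.values), name="price"
    )
    eils = eil_series_from_prices(prices, **CASE_STUDY_CONSTANTS)
    return prices, eils
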