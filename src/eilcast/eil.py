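"""Deterministic economic-injury-level (EIL) skeleton.

The EIL is the pest density at which the cost of damage equals the cost of
control.  It is built from five primary variables,

    EIL = C / (V * I * D * K)

where C is the cost of the management tactic per production unit, V the
commodity price per yield unit, I the injury units per pest, D the damage
(yield loss) per unit injury, and K the proportionate reduction of injury
averted by the tactic.  I*D is the slope b of the linear damage function
Y = a + b*x (a fixed to 0), i.e. the yield loss per pest.

This module also defines :class:`YearlySeries`, the ordered yearly series
container used throughout the package: holding V it is the price driver,
holding C/(V I D K) it is the EIL process that the stochastic machinery
models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = [
    "EILParameters",
    "DamageFunction",
    "YearlySeries",
    "compute_eil",
    "damage_slope",
    "eil_series_from_prices",
]


@dataclass(frozen=True)
class EILParameters:
    """The five primary EIL variables for one production year.

    Units are free-text metadata; the formula is unit-agnostic as long as
    C/(V*I*D) comes out in pests per sampling unit.
    """

    C: float  #: cost of management tactic per production unit (currency/area)
    V: float  #: price of commodity (currency/yield unit)
    I: float  #: injury units per pest
    D: float  #: damage (yield loss) per unit injury
    K: float  #: proportionate reduction of injury averted, in (0, 1]
    units: str = ""  #: optional free-text unit annotation

    def __post_init__(self) -> None:
        for name in ("C", "V", "I", "D"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise DomainError(f"EIL parameter {name} must be finite and > 0, got {value!r}")
        if not np.isfinite(self.K) or not 0 < self.K <= 1:
            raise DomainError(f"EIL parameter K must lie in (0, 1], got {self.K!r}")


@dataclass(frozen=True)
class DamageFunction:
    """Linear damage function Y = a + b*x with a = 0 by convention.

    b = I*D (sometimes written D') is the yield loss per pest.
    """

    b: float
    a: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.b) or self.b <= 0:
            raise DomainError(f"damage-function slope b must be finite and > 0, got {self.b!r}")

    def __call__(self, x):
        """Yield loss at pest density x."""
        return self.a + self.b * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class YearlySeries:
    """Ordered (year, value) pairs at yearly resolution.

    Years must be strictly increasing and consecutive: the AR machinery
    assumes equally spaced observations, so gaps are rejected rather than
    imputed.
    """

    years: np.ndarray
    values: np.ndarray
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        years = np.asarray(self.years)
        values = np.asarray(self.values, dtype=float)
        if years.ndim != 1 or values.ndim != 1 or len(years) != len(values):
            raise DomainError("years and values must be 1-d arrays of equal length")
        if len(years) < 2:
            raise DomainError(f"a yearly series needs at least 2 observations, got {len(years)}")
        if not np.issubdtype(years.dtype, np.integer):
            as_int = years.astype(int)
            if not np.array_equal(as_int, years):
                raise DomainError("years must be integers")
            years = as_int
        if np.any(np.diff(years) != 1):
            raise DomainError("years must be strictly increasing and consecutive (step 1)")
        if not np.all(np.isfinite(values)):
            raise DomainError("all series values must be finite")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    @property
    def end_year(self) -> int:
        return int(self.years[-1])


def compute_eil(params: EILParameters) -> float:
    """Pointwise EIL = C / (V*I*D*K), in pests per sampling unit.

    Strictly increasing in C and strictly decreasing in each of V, I, D, K;
    parameter validity is enforced by :class:`EILParameters`.
    """
    return params.C / (params.V * params.I * params.D * params.K)


def damage_slope(I: float, D: float) -> DamageFunction:
    """Damage function with slope b = I*D and intercept 0.

    I is injury per pest, D yield loss per unit injury; their product is the
    per-pest yield loss that links pest counts to economic damage.
    """
    if not np.isfinite(I) or I <= 0:
        raise DomainError(f"I must be finite and > 0, got {I!r}")
    if not np.isfinite(D) or D <= 0:
        raise DomainError(f"D must be finite and > 0, got {D!r}")
    return DamageFunction(b=I * D)


def eil_series_from_prices(
    prices: YearlySeries, *, C: float, I: float, D: float, K: float
) -> YearlySeries:
    """Yearly EIL series driven by yearly commodity prices.

    All variables except the commodity price V are held constant across
    years; year t gets EIL_t = C / (V_t * I * D * K).  Output years equal
    the input years.
    """
    for year, price in zip(prices.years, prices.values):
        if price <= 0:
            raise DomainError(f"commodity price for year {int(year)} must be > 0, got {price!r}")
    eils = np.array(
        [compute_eil(EILParameters(C=C, V=v, I=I, D=D, K=K)) for v in prices.values]
    )
    return YearlySeries(years=prices.years.copy(), values=eils, name="EIL")
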