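"""Exception hierarchy shared across the package."""


class EilcastError(Exception):
    """Base class for all package-specific errors."""


class DomainError(EilcastError, ValueError):
    """An input violates a mathematical precondition (sign, range, shape)."""


class InsufficientDataError(DomainError):
    """The series is too short for the requested operation."""


class NonStationaryError(DomainError):
    """AR coefficients have a characteristic root on or inside the unit circle."""


class ConvergenceError(EilcastError, RuntimeError):
    """The likelihood optimizer failed to converge.

    Carries the last iterate so the failure can be diagnosed.
    """

    def __init__(self, message: str, last_objective: float | None = None,
                 last_params=None):
        super().__init__(message)
        self.last_objective = last_objective
        self.last_params = last_params


class SeriesFormatError(EilcastError, ValueError):
    """A series file is malformed (bad header, non-numeric, year gaps)."""
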