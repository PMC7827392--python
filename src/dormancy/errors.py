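"""Exception hierarchy for the dormancy package."""


class DormancyError(Exception):
    """Base class for all package errors."""


class ParameterValidationError(DormancyError, ValueError):
    """A model constant or initial condition violates its constraints."""


class DomainError(DormancyError, ValueError):
    """A state or argument is outside the mathematical domain of an operation."""


class ConfigError(DormancyError, ValueError):
    """A run configuration (schedule, grid, protocol) is inconsistent."""


class IntegrationError(DormancyError, RuntimeError):
    """The solver produced a non-finite state.

    Attributes
    ----------
    last_valid_time : float
        Last time (days) at which the state was finite.
    """

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class ClassificationError(DormancyError, ValueError):
    """A trajectory cannot be assigned a fate (e.g. it does not span the horizon)."""


class FitError(DormancyError, RuntimeError):
    """Parameter estimation failed to converge.

    Attributes
    ----------
    best : FitResult or None
        Best incumbent found before failure.
    """

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best
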