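"""Exception hierarchy shared across the package."""


class CalregError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CalregError, ValueError):
    """A parameter violates its documented domain."""


class ConfigurationError(CalregError, ValueError):
    """A configuration file or section is malformed."""


class IntegrationError(CalregError, RuntimeError):
    """The ODE solver failed; carries the model time of failure."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class NumericalStateError(CalregError, RuntimeError):
    """A state vector contains NaN/Inf; names the offending component."""


class SlowFastError(CalregError, RuntimeError):
    """The time-scale separation assumed by the averaged method is violated."""


class TraceFormatError(CalregError, ValueError):
    """A trace file is malformed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line
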