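"""Exception and warning types used across the package."""


class RespigateError(Exception):
    """Base class for all package errors."""


class InputError(RespigateError, ValueError):
    """Invalid input data (wrong shape, too short, out of order, ...)."""


class ParameterError(RespigateError, ValueError):
    """Invalid configuration or model parameter."""


class DegenerateResultError(RespigateError, ArithmeticError):
    """A statistic is undefined for this input (e.g. zero variance)."""


class ConvergenceWarning(UserWarning):
    """An iterative solver stopped at its iteration limit."""
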