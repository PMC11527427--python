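"""Exception types shared across the package."""


class FiloquantError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FiloquantError, ValueError):
    """A parameter violates its documented domain (e.g. nonpositive gain)."""


class InsufficientDataError(FiloquantError, ValueError):
    """Too few observations to compute the requested quantity."""


class UnstableCalibrationError(FiloquantError, ArithmeticError):
    """Slope confidence bounds cross zero; molecule CIs would be unbounded."""


class DegenerateTestError(FiloquantError, ArithmeticError):
    """A statistical test is undefined (zero variance, constant ranks)."""


class UndefinedStatisticError(FiloquantError, ArithmeticError):
    """A requested statistic has no defined value for the given input."""
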