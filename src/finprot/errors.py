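"""Exception hierarchy shared across the package.

Each CLI-visible error class maps to a distinct nonzero exit code so that
shell pipelines can distinguish configuration mistakes from bad data.
"""


class FinprotError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(FinprotError):
    """Invalid or incomplete configuration (missing column, bad mapping...)."""

    exit_code = 3


class InputError(FinprotError):
    """Unusable input data (empty file, empty vector, N too small...)."""

    exit_code = 4


class ValidationError(FinprotError):
    """A household record violates an invariant under the strict policy."""

    exit_code = 5


class DegenerateDenominatorError(FinprotError):
    """Zero capacity-to-pay with positive OOP under the strict policy."""

    exit_code = 6


class CalibrationError(FinprotError):
    """The bisection calibrator failed to bracket or converge."""

    exit_code = 7


class UndefinedIndexError(FinprotError):
    """Concentration index requested for a zero-mean outcome."""

    exit_code = 8
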