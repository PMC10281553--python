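"""Exception hierarchy for bifurscan.

Every error raised deliberately by the library derives from
:class:`BifurscanError`, so callers (and the CLI) can catch one type.
"""


class BifurscanError(Exception):
    """Base class for all bifurscan errors."""

    #: short machine-parsable code, used by the CLI
    code = "error"


class InvalidNetworkError(BifurscanError):
    """Network construction parameters are inconsistent."""

    code = "invalid-network"


class DomainError(BifurscanError):
    """An input value is outside the mathematical domain of an operation."""

    code = "domain"


class BracketingError(BifurscanError):
    """A root bracket does not contain a sign change of the tracked indicator."""

    code = "bracketing"


class InstabilityError(BifurscanError):
    """Numerical integration produced non-finite values."""

    code = "instability"


class StabilityError(BifurscanError):
    """A matrix required to be Hurwitz (all eigenvalues in the left half plane) is not."""

    code = "not-hurwitz"


class ShapeError(BifurscanError):
    """Array dimensions are inconsistent."""

    code = "shape"


class UndefinedStatisticError(BifurscanError):
    """A statistic (covariance, correlation) is undefined for the given input."""

    code = "undefined-statistic"


class FormatError(BifurscanError):
    """A file does not conform to its declared format."""

    code = "format"


class ConfigError(BifurscanError):
    """Invalid configuration or threshold values."""

    code = "config"


class DegenerateInputError(BifurscanError):
    """Input is degenerate for the requested model fit (e.g. zero variance)."""

    code = "degenerate"
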