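"""Exception hierarchy.

All errors raised by this package derive from :class:`FHTBoostError`, so
callers can catch one type. Numerical-failure signals are separated from
user errors because they are recoverable (typically by lowering the
boosting step size).
"""


class FHTBoostError(Exception):
    """Base class for all fhtboost errors."""


class DomainError(FHTBoostError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class SchemaError(FHTBoostError, ValueError):
    """An input table does not match the declared column roles or types."""


class ConfigError(FHTBoostError, ValueError):
    """An invalid configuration value."""


class NumericalFailure(FHTBoostError, ArithmeticError):
    """A likelihood or gradient evaluation left the representable range.

    Carries enough context (iteration, offending quantity) for the caller
    to retry with a smaller step size.
    """

    def __init__(self, message: str, *, iteration: int | None = None,
                 quantity: str | None = None):
        super().__init__(message)
        self.iteration = iteration
        self.quantity = quantity


class FittingError(FHTBoostError, RuntimeError):
    """Model fitting failed (e.g. optimizer non-convergence).

    ``detail`` holds the optimizer trace or the triggering exception.
    """

    def __init__(self, message: str, *, detail=None):
        super().__init__(message)
        self.detail = detail
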