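"""Exception hierarchy shared across the package."""


class PassagefitError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PassagefitError, ValueError):
    """A function argument violates its documented precondition."""


class ConfigurationError(PassagefitError, ValueError):
    """An inconsistent configuration (e.g. ambiguous barcodes, duplicate targets)."""


class RecursionOverflowError(PassagefitError, ArithmeticError):
    """The un-normalized frequency recursion left [0, 1].

    The multiplicative recursion ``p * w**dg`` is only a valid frequency
    update while the product stays in [0, 1]; for strong selection or long
    intervals use the normalized variant instead.
    """


class UndefinedFrequencyError(PassagefitError, ZeroDivisionError):
    """Genotype frequency requested for a sample with zero informative reads."""


class ConvergenceError(PassagefitError, RuntimeError):
    """MCMC sampling failed its convergence contract.

    Carries the diagnostics that triggered the failure in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ValidationError(PassagefitError, ValueError):
    """A workflow configuration failed schema validation (exit code 2)."""


class StageError(PassagefitError, RuntimeError):
    """A workflow stage failed at run time (exit code 3)."""
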