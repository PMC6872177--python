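"""Exception hierarchy for erythropy."""


class ErythropyError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ErythropyError, ValueError):
    """A model or configuration parameter is out of its admissible range."""


class InvalidInputError(ErythropyError, ValueError):
    """Input data violate a precondition (negative counts, bad shapes...)."""


class UndefinedFractionError(ErythropyError, ZeroDivisionError):
    """The differentiated fraction is requested where the total population is zero."""


class SchemaError(ErythropyError, ValueError):
    """A CSV file does not conform to the expected schema."""


class ConvergenceError(ErythropyError, RuntimeError):
    """No optimizer restart converged; carries the best attempt found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class UndefinedCriterionError(ErythropyError, ValueError):
    """AICc is undefined for the given sample size / parameter count."""
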