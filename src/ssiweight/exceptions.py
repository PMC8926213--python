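"""Exception hierarchy for the ssiweight pipeline."""


class SSIWeightError(Exception):
    """Base class for all ssiweight errors."""


class InvalidInputError(SSIWeightError, ValueError):
    """A value violates a precondition (negative mass, non-positive dimension, ...)."""


class DegenerateIntervalError(InvalidInputError):
    """Interval has zero or negative width; the splitting procedure is undefined."""


class InconsistentProbeError(InvalidInputError):
    """A probe does not lie strictly inside the interval it is meant to split."""


class IncompleteTrialError(SSIWeightError):
    """An SSI trial is missing intervals or answers required by the operation."""


class InsufficientDataError(SSIWeightError):
    """Too few observations for the statistic (e.g. an SD needs at least two)."""


class EmptyInputError(SSIWeightError):
    """An operation received an empty table or value list."""


class DegenerateFitError(SSIWeightError):
    """Regression/correlation input is degenerate (constant predictor, n < 3)."""


class ConfigurationError(SSIWeightError):
    """Inconsistent run configuration (model count, participant count, paths)."""


class TrialTableValidationError(SSIWeightError):
    """A trial table violates the schema or the SSI trial invariants.

    Carries the offending row numbers (0-based positions in the table).
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class MissingTrialWarning(UserWarning):
    """A comparison pair was skipped because one of its trials is missing."""
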