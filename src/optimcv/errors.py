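"""Exception hierarchy for optimcv."""


class OptimcvError(Exception):
    """Base class for all optimcv-specific errors."""


class UndefinedConcordanceError(OptimcvError):
    """Raised when a C statistic is requested for data lacking cases or controls."""


class DegenerateDesignError(OptimcvError):
    """Raised when a design matrix is rank-deficient after dropping constant columns.

    The offending column names (or indices) are carried in ``columns``.
    """

    def __init__(self, message: str, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class InfeasibleFoldsError(OptimcvError):
    """Raised when a fold/split scheme cannot give every fold both outcome classes."""


class CalibrationError(OptimcvError):
    """Raised when the coefficient scale constant cannot reach the target C."""


class TooFewEventsError(OptimcvError):
    """Raised when a Monte-Carlo sample contains too few events for a stable estimate."""
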