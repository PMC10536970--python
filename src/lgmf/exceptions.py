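"""Exception types shared across the package."""


class LgmfError(Exception):
    """Base class for package errors."""


class DimensionMismatchError(LgmfError, ValueError):
    """A geometry does not match the coordinate dimension of a surface."""


class SingularMatrixError(LgmfError, ValueError):
    """A linear solve met a singular (or indefinite-where-forbidden) matrix."""


class ConstraintUnreachableError(LgmfError, RuntimeError):
    """The requested force-magnitude level set is empty in the search region."""


class ConvergenceError(LgmfError, RuntimeError):
    """An iterative stage exhausted its iteration budget.

    Carries the best diagnostic value seen so the caller can decide whether
    to retry with a smaller step.
    """

    def __init__(self, message: str, best_cos_alpha: float | None = None):
        super().__init__(message)
        self.best_cos_alpha = best_cos_alpha
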