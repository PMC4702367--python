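"""Exception hierarchy shared across the package."""


class TvccError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TvccError, ValueError):
    """Invalid study configuration (unknown control definition, bad grid, ...)."""


class DataError(TvccError, ValueError):
    """Subject data violate the schema invariants."""


class PeriodAssignmentError(TvccError, ValueError):
    """A time falls outside the period grid."""


class SeparationError(TvccError, RuntimeError):
    """The likelihood has no finite maximiser (perfect separation or an
    inestimable parameter, e.g. a period with cases but no controls)."""


class ConvergenceError(TvccError, RuntimeError):
    """Newton iterations failed to converge.

    Carries the last iterate so the failure can be inspected.
    """

    def __init__(self, message, params=None, grad_norm=None, n_iter=None):
        super().__init__(message)
        self.params = params
        self.grad_norm = grad_norm
        self.n_iter = n_iter


class SingularInformationError(TvccError, RuntimeError):
    """The observed information matrix is singular."""


class SimulationError(TvccError, RuntimeError):
    """The data-generating process could not satisfy the request
    (e.g. a birth cohort's control pool is smaller than its case count)."""
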