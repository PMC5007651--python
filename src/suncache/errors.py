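"""Exception hierarchy shared across the pipeline."""


class SuncacheError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SuncacheError):
    """Malformed or out-of-range input."""


class NoSunEventError(SuncacheError):
    """Sunrise/sunset undefined (polar day or night)."""


class ProjectionDomainError(SuncacheError):
    """Point too far from the projection origin for planar geometry."""


class UndefinedBearingError(SuncacheError):
    """Zero displacement between start and stop."""


class DegenerateTrackError(SuncacheError):
    """All fixes coincident; no geometry to compute."""


class InsufficientDataError(SuncacheError):
    """Sample too small for the requested statistic."""


class ConvergenceError(SuncacheError):
    """Iterative fit failed to converge; may carry the best fit found."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class InvalidComparisonError(SuncacheError):
    """Model/run comparison requested between incompatible objects."""


class InvalidConfigError(SuncacheError):
    """Synthetic-data configuration is infeasible."""
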