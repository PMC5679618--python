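"""Exception hierarchy for the pondpredict package."""


class PondPredictError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PondPredictError):
    """A configuration value (band map, threshold, archetype) is invalid."""


class InputError(PondPredictError):
    """Caller-supplied data violates a documented precondition."""


class AlignmentError(PondPredictError):
    """Two rasters that must share a grid do not."""


class EstimationError(PondPredictError):
    """Not enough (or no) qualifying data to produce an estimate."""


class DegenerateFitError(EstimationError):
    """Zero-residual fit: predictability is infinite, not a finite number."""
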