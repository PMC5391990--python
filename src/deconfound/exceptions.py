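"""Exception hierarchy for deconfound."""


class DeconfoundError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DeconfoundError):
    """Input data violates a structural invariant (missing values, bad shapes)."""


class AlignmentError(DeconfoundError):
    """Subject identifiers do not align across input sources."""


class SingularMatrixError(DeconfoundError):
    """A design matrix is rank deficient where full column rank is required."""


class NumericalError(DeconfoundError):
    """A numerical operation failed (e.g. Cholesky after maximum jitter)."""


class FitError(DeconfoundError):
    """Model fitting failed on all optimizer restarts."""


class WeightingError(DeconfoundError):
    """Instance-weight computation produced non-finite or non-positive values."""


class SamplingError(DeconfoundError):
    """Biased/unbiased sample drawing could not satisfy its acceptance rule."""


class MetricError(DeconfoundError):
    """An evaluation metric is undefined for the given partition (empty cell)."""
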