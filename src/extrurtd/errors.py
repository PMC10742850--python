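"""Typed errors shared across the package."""


class ExtruRTDError(Exception):
    """Base class for all package errors."""


class UnnormalizableSeriesError(ExtruRTDError):
    """Tracer signal carries no mass after baseline subtraction."""


class NumericalInconsistencyError(ExtruRTDError):
    """A computed quantity violates a mathematical bound beyond rounding."""


class PecletDomainError(ExtruRTDError):
    """sigma_theta^2 outside (0, 1): the closed-vessel relation has no root."""


class DegenerateFitError(ExtruRTDError):
    """Regression input has no usable variation."""


class FeedSpecError(ExtruRTDError):
    """Moisture/feed specification out of its physical domain."""


class TrainingDivergenceError(ExtruRTDError):
    """Gradient descent produced non-finite loss."""
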