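"""Exception types raised by the detection pipeline."""


class SymaxisError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SymaxisError, ValueError):
    """Raised for malformed inputs (empty images, empty verdict lists, ...)."""


class InvalidParameterError(SymaxisError, ValueError):
    """Raised for parameter values outside their documented domain."""


class InsufficientFeaturesError(SymaxisError, ValueError):
    """Raised when too few keypoints survive to define a centroid."""


class NoAxisError(SymaxisError, ValueError):
    """Raised when an operation requires a symmetric verdict and there is none."""
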