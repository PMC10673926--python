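"""Exception hierarchy shared across the package."""


class ClonalFishError(Exception):
    """Base class for all package errors."""


class ValidationError(ClonalFishError):
    """A configuration or data-model invariant is violated; names the field."""


class FormatError(ClonalFishError):
    """Malformed input table (non-monotone timestamps, duplicate samples, ...)."""


class InsufficientDataError(ClonalFishError):
    """Too few observations to compute the requested quantity."""


class AggregationError(ClonalFishError):
    """Duplicate or conflicting records encountered while summarising."""


class RankError(ClonalFishError):
    """Singular fixed-effects design; message names the collinear columns."""


class ConvergenceError(ClonalFishError):
    """An iterative fit failed to converge."""


class CIUnreliableError(ClonalFishError):
    """Too many refit failures during simulation-based confidence intervals."""


class AlignmentError(ClonalFishError):
    """Individual sets do not line up across pipeline stages."""
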