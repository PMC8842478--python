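"""Exception types raised across the pipeline."""


class KcpachyError(Exception):
    """Base class for all package-specific errors."""


class MalformedMaskError(KcpachyError):
    """A label mask violates the background/epithelium/stroma column ordering."""


class EmptyMaskError(KcpachyError):
    """A label mask contains no tissue pixels at all."""


class ExtractionFailureError(KcpachyError):
    """Image-based boundary extraction failed on too many columns."""


class NoIntersectionError(KcpachyError):
    """A normal ray did not intersect the target boundary within the search cap."""


class CoverageError(KcpachyError):
    """A boundary trace does not cover the requested region of interest."""


class InsufficientDataError(KcpachyError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(KcpachyError):
    """Input data carry no variance/separation for the requested statistic."""


class DegenerateModelError(KcpachyError):
    """Discriminant fitting failed (identical classes or singular covariance)."""
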