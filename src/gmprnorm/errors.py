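"""Exception hierarchy shared across the package."""


class GmprNormError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GmprNormError):
    """Raised when an input table, label file, or parameter set is malformed."""


class NormalizationError(GmprNormError):
    """Raised when a size-factor method cannot produce factors for a table."""


class RLEFailureError(NormalizationError):
    """RLE fails: no feature is observed in every sample.

    The median-of-ratios reference requires at least one zero-free feature
    when no pseudo-count is added; sparse tables frequently have none.
    """
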