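"""Exception hierarchy shared across the package."""


class GsvdNmfError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(GsvdNmfError, ValueError):
    """Incompatible or out-of-range array dimensions."""


class ValidationError(GsvdNmfError, ValueError):
    """Input values violate a precondition (non-finite, negative, ...)."""


class UnsupportedRankError(GsvdNmfError, ValueError):
    """Requested rank is outside the range the method supports."""


class DegeneratePairError(GsvdNmfError, ValueError):
    """A matrix pair is too ill-conditioned for a meaningful GSVD."""


class DegenerateDirectionsError(GsvdNmfError, ValueError):
    """Proposed coefficient rows are singular (zero or duplicate rows)."""


class UndefinedMetricError(GsvdNmfError, ValueError):
    """A quality metric is undefined for this input (e.g. all-zero X)."""


class NumericError(GsvdNmfError, RuntimeError):
    """A numeric failure (non-finite intermediate) during iteration."""
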