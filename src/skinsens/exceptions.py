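"""Exception types shared across the package."""


class SkinSensError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(SkinSensError, ValueError):
    """An argument violates a documented precondition."""


class NormalizationError(SkinSensError):
    """Plate normalization failed (no DMSO wells, or zero DMSO median)."""


class InsufficientDataError(SkinSensError):
    """Too few data points for the requested computation."""


class MissingDataError(SkinSensError):
    """Required information sources are absent."""
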