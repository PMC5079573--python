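"""Exception hierarchy shared across the package."""


class KinstyleError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(KinstyleError, ValueError):
    """An argument violates a documented precondition."""


class NoMovementError(KinstyleError):
    """Wrist speed never exceeds the onset threshold."""


class TruncatedTrialError(KinstyleError):
    """Wrist speed never drops back below the threshold after onset."""


class DegenerateFrameError(KinstyleError):
    """Hand-frame markers are collinear; no local frame exists."""


class DegeneratePlaneError(KinstyleError):
    """Plane-defining markers are collinear; no unit normal exists."""


class InsufficientDataError(KinstyleError):
    """Not enough observations for the requested statistic."""


class SchemaError(KinstyleError):
    """An input table does not match any recognized layout."""
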