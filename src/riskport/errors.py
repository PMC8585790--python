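"""Exception hierarchy shared by all riskport modules."""


class RiskportError(Exception):
    """Base class for all riskport errors."""

    category = "error"


class ValidationError(RiskportError, ValueError):
    """Input violates a documented invariant (bad value, duplicate key, ...)."""

    category = "validation"


class FormatError(RiskportError, ValueError):
    """A file could not be parsed against its declared schema."""

    category = "format"


class FittingError(RiskportError, RuntimeError):
    """Model fitting failed to converge."""

    category = "fitting"
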