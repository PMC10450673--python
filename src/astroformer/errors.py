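"""Exception types shared across the circuit and feature-map modules."""


class AstroformerError(Exception):
    """Base class for errors raised by this package."""


class NumericRangeError(AstroformerError, ArithmeticError):
    """A computation produced a non-finite value (e.g. overflow in exp)."""


class DegenerateNormalizationError(AstroformerError, ArithmeticError):
    """The divisive-normalization denominator is too close to zero."""


class NotWrittenError(AstroformerError, RuntimeError):
    """The reading phase was entered before any token was written."""
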