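"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A physical or geometric parameter is outside its valid domain."""


class DimensionError(ValueError):
    """Two gridded quantities do not share a compatible shape."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class DegenerateHistogramError(ValueError):
    """Thresholding was requested on data with too few distinct values."""
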