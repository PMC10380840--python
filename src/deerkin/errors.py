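"""Package-wide exception types."""


class DeerkinError(Exception):
    """Base class for all deerkin errors."""


class InvalidInputError(DeerkinError, ValueError):
    """An argument violates a documented precondition."""


class ParseError(DeerkinError, ValueError):
    """A data file could not be parsed."""


class FitFailureError(DeerkinError, RuntimeError):
    """A fitting routine failed to converge or was handed degenerate data."""
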