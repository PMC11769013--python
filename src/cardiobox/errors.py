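"""Exception hierarchy."""


class CardioboxError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(CardioboxError):
    """A scalar input violates its precondition (names the offending field)."""


class ConfigurationError(CardioboxError):
    """Required configuration (e.g. an allometric exponent) is missing."""


class EmptyDataError(CardioboxError):
    """An operation that needs data received none."""


class InvalidDataError(CardioboxError):
    """Input data contain non-finite or otherwise unusable values."""


class InsufficientReferenceError(CardioboxError):
    """Not enough reference animals to build a summary (no healthy records)."""


class InconsistentReferenceError(CardioboxError):
    """Percentile summaries violate the ordering the grid construction needs."""


class InvalidSummaryError(CardioboxError):
    """A percentile summary is malformed (non-monotone anchors)."""


class RenderError(CardioboxError):
    """The chart cannot be drawn from the given profile."""
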