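"""Exception hierarchy for the pipeline.

All errors derive from :class:`HmolocusError` (itself a ``ValueError``) so
callers can catch everything from this package with one handler while
normal ``ValueError`` semantics are preserved.
"""


class HmolocusError(ValueError):
    """Base class for all errors raised by this package."""


class InvalidParameterError(HmolocusError):
    """A parameter is outside its documented domain."""


class InvalidInputError(HmolocusError):
    """An input object violates a precondition (empty sequence, missing anchor, ...)."""


class ConsistencyError(HmolocusError):
    """Cross-referenced inputs disagree (hit for an unknown gene, genome without SGB, ...)."""


class ParseError(HmolocusError):
    """A file could not be parsed; the message names the offending record."""


class UndefinedRatioError(HmolocusError):
    """A prevalence ratio was requested with a zero denominator."""
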