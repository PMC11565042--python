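"""Exception hierarchy for trialqc.

All errors raised by the library derive from :class:`TrialQCError` so callers
(and the CLI) can distinguish domain failures from programming errors.
"""


class TrialQCError(Exception):
    """Base class for all trialqc errors."""


class FormatError(TrialQCError):
    """Input file does not match the expected layout (e.g. missing column)."""


class ParseError(TrialQCError):
    """A cell could not be parsed as a number; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class IntegrityError(TrialQCError):
    """Table-level invariant violated (duplicate trials, non-finite values)."""


class InsufficientSampleError(TrialQCError):
    """Too few eligible participants for a defined estimate."""


class UndefinedEffectError(TrialQCError):
    """Effect size undefined (zero standard deviation)."""
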