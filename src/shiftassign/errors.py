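"""Exception hierarchy.

Every error raised by this package derives from :class:`ShiftAssignError`,
so callers (and the CLI) can distinguish our validation failures from
programming errors.
"""


class ShiftAssignError(Exception):
    """Base class for all shiftassign errors."""


class FormatError(ShiftAssignError):
    """A file could not be parsed: missing column, malformed block, bad header."""


class ValidationError(ShiftAssignError):
    """Parsed content violates an invariant (non-positive sigma, duplicate id, ...)."""


class UsageError(ShiftAssignError):
    """An operation was called with arguments outside its contract."""


class BlockSizeError(ShiftAssignError):
    """An assignment block exceeds the exact-computation size limits."""


class InfeasibleError(ShiftAssignError):
    """No assignment with nonzero posterior probability exists."""
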