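"""Exception hierarchy shared across the toolkit."""


class CorticoxError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(CorticoxError, ValueError):
    """A supplied parameter violates an operation's preconditions."""


class OutOfModelError(CorticoxError, ValueError):
    """An observation lies outside the invertible range of a forward model."""


class DegenerateInputError(CorticoxError, ValueError):
    """Input carries no information for the requested estimate."""


class EmptyResultError(CorticoxError, ValueError):
    """An operation produced no valid output (e.g. no valid pixels)."""


class InfeasibleScheduleError(CorticoxError, ValueError):
    """A pulse train or acquisition schedule is physically impossible."""


class FormatError(CorticoxError, ValueError):
    """An on-disk artifact does not match its expected format."""
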