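"""Exception hierarchy shared across the pipeline stages."""


class TermnetError(Exception):
    """Base class for all package errors."""


class ParseError(TermnetError):
    """An input table row could not be interpreted."""


class ValidationError(TermnetError):
    """A constructed object violates a structural invariant."""


class DomainError(TermnetError):
    """Arguments are outside an operation's mathematical domain."""
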