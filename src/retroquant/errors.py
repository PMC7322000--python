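"""Exception hierarchy shared across the package."""


class RetroquantError(Exception):
    """Base class for all package errors."""


class ParseError(RetroquantError):
    """A file could not be parsed; the message names the file and line."""


class ValidationError(RetroquantError):
    """Input violated a documented precondition or invariant."""


class UsageError(RetroquantError):
    """An API or CLI argument was outside its documented domain."""
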