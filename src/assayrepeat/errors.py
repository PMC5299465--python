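"""Exception hierarchy.

All package-raised errors derive from :class:`AssayRepeatError` so callers
(and the CLI) can distinguish user/data problems from genuine bugs.
"""


class AssayRepeatError(Exception):
    """Base class for all errors raised by assayrepeat."""


class FormatError(AssayRepeatError):
    """A file does not conform to the expected layout (missing columns, ...)."""


class ParseError(AssayRepeatError):
    """A value could not be parsed as a number."""


class DomainError(AssayRepeatError, ValueError):
    """An argument lies outside its mathematical domain (e.g. log2 of 0)."""


class DesignError(AssayRepeatError):
    """The replication design cannot support the requested estimation."""


class DataError(AssayRepeatError):
    """Non-finite or otherwise unusable observed values."""


class ParameterError(AssayRepeatError, ValueError):
    """An invalid tuning parameter or option."""
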