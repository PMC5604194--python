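"""Exception hierarchy shared by all hrvkit modules."""


class HRVError(Exception):
    """Base class for all hrvkit errors."""


class ValidationError(HRVError, ValueError):
    """An argument or data value violates a documented precondition."""


class ParseError(HRVError, ValueError):
    """A text input could not be parsed; the message names the offending line."""


class FormatError(ParseError):
    """A file is structurally not in the expected format (e.g. missing section)."""


class EmptyInputError(HRVError, ValueError):
    """A file or series contained no usable data."""


class InsufficientDataError(HRVError, ValueError):
    """The input is too short for the requested operation."""
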