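"""Exception types shared across readers and analyses."""


class DriverlensError(Exception):
    """Base class for package errors."""


class FormatError(DriverlensError, ValueError):
    """A file does not conform to its declared format."""


class ValidationError(DriverlensError, ValueError):
    """Well-formed input carries values outside the documented domain."""
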