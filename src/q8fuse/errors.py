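"""Exception hierarchy."""


class Q8FuseError(Exception):
    """Base class for package errors."""


class FormatError(Q8FuseError):
    """A file or array does not have the expected shape or layout."""


class ValidationError(Q8FuseError):
    """Well-formed input violates a semantic invariant."""
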