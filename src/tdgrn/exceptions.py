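"""Exception hierarchy: format errors (malformed files) vs validation errors
(well-formed input violating a model precondition)."""


class TdgrnError(ValueError):
    """Base class for all package errors."""


class FormatError(TdgrnError):
    """A file does not conform to its declared dialect."""


class ValidationError(TdgrnError):
    """Input is parseable but violates a domain invariant."""
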