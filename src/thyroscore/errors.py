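"""Exception hierarchy shared across the package."""


class ThyroscoreError(Exception):
    """Base class for all package errors."""


class InputError(ThyroscoreError):
    """A file or stream could not be read in the expected format."""


class ValidationError(ThyroscoreError):
    """Input was readable but violates a documented invariant."""


class OutputError(ThyroscoreError):
    """A result could not be written to its destination."""
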