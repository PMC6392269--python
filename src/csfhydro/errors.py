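"""Exception types shared across the package."""


class CsfHydroError(Exception):
    """Base class for all package errors."""


class FormatError(CsfHydroError, ValueError):
    """A file could not be parsed as the expected format."""


class ValidationError(CsfHydroError, ValueError):
    """An input violated a documented precondition or invariant."""
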