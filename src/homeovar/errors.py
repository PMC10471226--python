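"""Typed exceptions shared across the package."""


class HomeovarError(Exception):
    """Base class for all package errors."""


class FormatError(HomeovarError, ValueError):
    """A file is structurally malformed (missing columns, unparseable rows)."""


class ValidationError(HomeovarError, ValueError):
    """Well-formed input that violates a domain invariant."""
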