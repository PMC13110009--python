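"""Exception hierarchy for dcimsi."""


class DcimsiError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedFormatError(DcimsiError):
    """A file is in a format (or mode) the package does not read."""


class IntegrityError(DcimsiError):
    """A native container is corrupt, truncated, or internally inconsistent."""


class ValidationError(DcimsiError, ValueError):
    """Inputs violate a documented precondition."""


class DegenerateInputError(DcimsiError, ValueError):
    """Input is technically well-formed but degenerate for the requested
    computation (all-zero spectrum under cosine, singleton class, ...)."""
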