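"""Exception types shared across the package."""


class SirenError(Exception):
    """Base class for all siren-specific errors."""


class DegenerateProfileError(SirenError):
    """Raised when an expression profile is constant.

    A constant profile has zero range, so it cannot be mapped onto the
    B-spline knot domain and carries no information about regulation sign.
    Callers typically catch this and mark the affected edges as unsigned.
    """


class DomainError(SirenError):
    """Raised when a scaled value lies outside the B-spline knot domain."""


class ShapeError(SirenError):
    """Raised when two inputs disagree on sample count or ordering."""


class ParseError(SirenError):
    """Raised on malformed expression or network input files."""


class DuplicateGeneError(ParseError):
    """Raised when an expression matrix contains repeated gene identifiers."""
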