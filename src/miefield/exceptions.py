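"""Exception hierarchy shared across the package."""


class MieFieldError(Exception):
    """Base class for all package errors."""


class ValidationError(MieFieldError, ValueError):
    """Input violates a documented precondition or type invariant."""


class ParseError(MieFieldError, ValueError):
    """Malformed input file; the message names the offending line."""


class SingularityError(MieFieldError, ValueError):
    """Evaluation requested at a singular abscissa (e.g. y_l or h_l at 0)."""


class DomainError(MieFieldError, ValueError):
    """Argument outside the mathematical domain of the function."""


class GeometryError(MieFieldError, ValueError):
    """Incompatible geometries (grid shape, pixel size, overlap)."""
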