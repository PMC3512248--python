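"""Exception hierarchy shared across the package.

Validation errors (bad input data) are kept distinct from runtime errors so
the CLI can map them onto exit codes 1 and 2 respectively.
"""


class LgtratesError(Exception):
    """Base class for all package errors."""


class ValidationError(LgtratesError):
    """Raised when input data violates a documented invariant."""


class NewickParseError(ValidationError):
    """Raised on malformed Newick input; carries a character offset when known."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class ConstraintConflictError(ValidationError):
    """Raised when age constraints are mutually infeasible."""

    def __init__(self, message: str, clades: tuple[str, ...] = ()):
        super().__init__(message)
        self.clades = clades
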