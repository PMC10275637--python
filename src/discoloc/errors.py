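"""Exception hierarchy shared across the package."""


class DiscolocError(Exception):
    """Base class for all package errors."""


class FormatError(DiscolocError, ValueError):
    """Malformed input file or out-of-contract values."""


class EmptyInputError(DiscolocError, ValueError):
    """No usable rows after validation."""


class EmptyOverlapError(DiscolocError, ValueError):
    """Two studies share no variants after harmonization."""


class IdLookupError(DiscolocError, KeyError):
    """Requested variant id(s) absent from a matrix or catalog."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"ids not found: {', '.join(map(str, self.missing[:10]))}"
                         + (" ..." if len(self.missing) > 10 else ""))


class AlignmentError(DiscolocError, ValueError):
    """Vectors or tables that must be aligned are not."""


class DomainError(DiscolocError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class SimulationError(DiscolocError, RuntimeError):
    """A simulator could not realize the requested configuration."""


class MissingSampleSizeError(DiscolocError, ValueError):
    """Operation requires per-variant sample size but none was provided."""


class DegenerateFitError(DiscolocError, ValueError):
    """Model fit is degenerate (zero residual variance or zero scale)."""
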