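"""Exception hierarchy shared across the package."""


class PairrankError(Exception):
    """Base class for all pairrank-specific errors."""


class ParseError(PairrankError):
    """A file could not be parsed into a valid in-memory object."""


class ValidationError(PairrankError):
    """An in-memory object violates its invariants."""


class FitError(PairrankError):
    """A statistical fit failed (non-convergence, separation, degeneracy)."""
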