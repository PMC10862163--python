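"""Exception hierarchy shared across the package."""


class PedgrmError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(PedgrmError, ValueError):
    """A configuration object violates one of its invariants."""


class PedigreeIntegrityError(PedgrmError, ValueError):
    """Pedigree is structurally invalid (cycle, missing genetic parent, ...)."""


class IdCollisionError(PedgrmError, ValueError):
    """Duplicate or colliding individual identifiers."""


class CoverageError(PedgrmError, ValueError):
    """An individual lacks the data required by an operation."""


class IdLookupError(PedgrmError, KeyError):
    """An identifier is absent from a matrix, pedigree or table."""


class UndefinedCorrelationError(PedgrmError, ValueError):
    """Correlation requested on a zero-variance vector."""


class DecompositionError(PedgrmError, ValueError):
    """A relatedness matrix could not be made positive definite."""


class EmptyResultError(PedgrmError, ValueError):
    """A filtering stage removed every remaining row or column."""

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        super().__init__(message or f"no data left after stage '{stage}'")


class InsufficientChainsError(PedgrmError, ValueError):
    """Convergence diagnostics need at least two chains."""
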