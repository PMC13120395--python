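"""Exception hierarchy shared across the pipeline."""


class CytomorphError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CytomorphError):
    """A required column is missing or mis-typed in an input table."""


class ValidationError(CytomorphError):
    """A record or table violates a domain invariant."""


class ParameterError(CytomorphError, ValueError):
    """A configuration or function parameter is outside its valid domain."""


class DegenerateTileError(CytomorphError):
    """A tile has too little colour structure to cluster (single colour)."""


class InsufficientTilesError(CytomorphError):
    """Fewer QC-accepted tiles are available than the number requested."""

    def __init__(self, accepted: int, required: int):
        self.accepted = accepted
        self.required = required
        super().__init__(
            f"only {accepted} QC-accepted tiles available, {required} required"
        )


class AggregationError(CytomorphError):
    """Case-level aggregation was attempted on an empty cell list."""
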