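"""Exception types shared across the pipeline."""


class EmobiasError(Exception):
    """Base class for all package errors."""


class SchemaError(EmobiasError, ValueError):
    """An input table violates its declared schema (column, enum, or index)."""


class DegenerateInputError(EmobiasError, ValueError):
    """Input is formally valid but statistically degenerate.

    Examples: a constant column passed to a z-score, an agreement matrix
    with a single distinct code (expected disagreement zero), or an ANOVA
    error stratum with zero sum of squares.
    """


class DesignError(EmobiasError, ValueError):
    """A model design is unusable: rank deficiency, empty design cells,
    or missing within-subject observations."""
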