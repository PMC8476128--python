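"""Exception types shared across the pipeline."""


class OrgenrichError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(OrgenrichError, ValueError):
    """A simulation or analysis configuration violates a precondition."""


class UnknownGeneError(OrgenrichError, KeyError):
    """A gene identifier is absent from the gene universe."""


class UnknownVariantError(OrgenrichError, KeyError):
    """A variant identifier is absent from the genotype matrix."""


class DegenerateDesignError(OrgenrichError, ValueError):
    """A regression design matrix is degenerate (constant or collinear)."""


class InvalidRecordError(OrgenrichError, ValueError):
    """An input record violates a table invariant (e.g. se <= 0)."""
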