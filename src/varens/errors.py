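"""Exception hierarchy shared across the pipeline stages."""


class VarensError(Exception):
    """Base class for all package errors."""


class DomainError(VarensError):
    """A stimulus parameter falls outside its feature bounds."""


class UnsupportedDesignError(VarensError):
    """A design request the stimulus generator cannot honor (e.g. even set size)."""


class EstimationError(VarensError):
    """A model fit cannot be estimated from the supplied trials."""


class UndefinedPSEError(EstimationError):
    """PSE requested from a fit with zero slope."""


class UndefinedJNDError(EstimationError):
    """JND requested from a fit with non-positive slope."""


class InsufficientSampleError(VarensError):
    """Too few participants for outlier screening or pooling."""


class PoolingError(VarensError):
    """No usable participant-level fits remain to pool."""


class SchemaError(VarensError):
    """A trial table does not conform to the tidy CSV schema."""
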