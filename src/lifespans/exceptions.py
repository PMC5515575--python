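"""Typed errors raised by validation and estimation routines."""


class LifespansError(Exception):
    """Base class for all package errors."""


class SchemaError(LifespansError):
    """A required column is missing or mis-named in an input table."""


class CohortValidationError(LifespansError):
    """A record or cohort violates the data contract (bad age, label, id)."""


class ParameterError(LifespansError):
    """A model or simulation parameter is outside its admissible range."""


class EstimationError(LifespansError):
    """An estimator cannot produce a result on the given input
    (undefined median, rank-deficient design, no covariate contrast...)."""
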