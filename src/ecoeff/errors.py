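"""Exception hierarchy shared across the pipeline stages."""


class EcoeffError(Exception):
    """Base class for all package errors."""


class SchemaError(EcoeffError):
    """A required column/role is missing from an input table."""


class IntegrityError(EcoeffError):
    """Keyed data violates a uniqueness or consistency requirement."""


class FormatError(EcoeffError):
    """A file does not conform to its declared on-disk format."""


class DomainError(EcoeffError):
    """A value lies outside the mathematical domain of an operation."""


class DegenerateInputError(EcoeffError):
    """Input is formally valid but the statistic is undefined on it
    (constant series, zero variance, no transitions...)."""


class ConvergenceError(EcoeffError):
    """An iterative estimator failed to converge; carries diagnostics."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace
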