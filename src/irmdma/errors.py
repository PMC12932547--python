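"""Typed exception hierarchy.

All data-validation failures raise subclasses of :class:`ValidationError`
so callers (and the CLI, which maps them to exit code 2) can distinguish
bad input from programming errors.
"""


class IrmdmaError(Exception):
    """Base class for all package errors."""


class ValidationError(IrmdmaError):
    """Input data violates a documented contract."""


class DuplicateIdentifierError(ValidationError):
    """A taxon or sample identifier occurs more than once."""


class DegenerateSampleError(ValidationError):
    """A sample column is unusable (e.g. sums to zero)."""


class DesignError(ValidationError):
    """The sample-design table is inconsistent or incomplete."""


class ConfigurationError(IrmdmaError):
    """An analysis was configured in a way that cannot be run."""


class UndefinedStatisticError(IrmdmaError):
    """A statistic is mathematically undefined for the given input."""


class NoCandidateError(IrmdmaError):
    """Automatic reference-taxon screening produced no passing candidate."""
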