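"""Exception hierarchy shared by all modules."""


class TractofitError(Exception):
    """Base class for package errors."""


class InvalidSchemeError(TractofitError):
    """Gradient scheme violates its invariants."""


class GeometryError(TractofitError):
    """Streamline or bundle geometry leaves the phantom grid."""


class ParameterError(TractofitError):
    """A numeric parameter is outside its admissible range."""


class ContractError(TractofitError):
    """Inconsistent shapes or mismatched inputs between stages."""


class DataError(TractofitError):
    """Non-finite or otherwise unusable data."""


class FormatError(TractofitError):
    """On-disk artifact is malformed."""


class DegenerateInputError(TractofitError):
    """Input is structurally degenerate (too few points, zero length...)."""


class UndefinedMetricError(TractofitError):
    """A graph metric is undefined for this input (e.g. n < 2)."""


class SingularDesignError(TractofitError):
    """Collinear design matrix in a statistical model."""


class InsufficientSampleError(TractofitError):
    """Too few subjects per group for the requested analysis."""
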