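"""Exception hierarchy shared by all strvar modules."""


class StrvarError(Exception):
    """Base class for all package errors."""


class InputError(StrvarError):
    """Malformed or out-of-contract input values."""


class SchemaError(InputError):
    """A table does not match its expected schema."""


class InsufficientDataError(StrvarError):
    """Too few observations to compute the requested statistic."""


class NormalizationError(StrvarError):
    """Rank normalization undefined (fewer than two items)."""


class EmptySubsetError(StrvarError):
    """A subset operation received no usable loci/genes."""


class UndefinedCorrelationError(StrvarError):
    """Correlation undefined: <2 shared cells or zero variance."""
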