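"""Exception hierarchy.

Every error raised by this package derives from :class:`AffectSCRError`, so
callers (and the CLI) can catch one type and map it to a nonzero exit status.
"""


class AffectSCRError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(AffectSCRError, ValueError):
    """A waveform parameter is non-finite or violates its sign constraint."""


class InvalidDataError(AffectSCRError, ValueError):
    """Input array contains non-finite values."""


class IncompatibleTracesError(AffectSCRError, ValueError):
    """Traces differ in length or sampling rate and cannot be combined."""


class EmptyInputError(AffectSCRError, ValueError):
    """An operation received an empty collection."""


class UnderdeterminedFitError(AffectSCRError, ValueError):
    """Fewer observations than free parameters."""


class TooFewValuesError(AffectSCRError, ValueError):
    """A sample is too small for the pairwise extension (n < 2)."""


class SchemaError(AffectSCRError, ValueError):
    """A table or serialized model does not match the expected schema."""


class ValidationError(AffectSCRError, ValueError):
    """Schema is right but a value violates an invariant (e.g. rating > 9)."""


class UndefinedCorrelationError(AffectSCRError, ValueError):
    """Pearson correlation undefined because one input has zero variance."""
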