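"""Exception hierarchy and warning categories.

Every error raised by the library derives from :class:`LemsurvError` and
carries a short machine-parseable ``category`` used by the CLI's one-line
error reporting.
"""


class LemsurvError(Exception):
    """Base class for all lemsurv errors."""

    category = "error"


class DomainError(LemsurvError, ValueError):
    """An argument is outside the mathematical domain of an operation."""

    category = "domain"


class ExtrapolationError(DomainError):
    """Concentration outside [0, C0] without the explicit extrapolation flag."""

    category = "extrapolation"


class ConfigurationError(LemsurvError):
    """Inconsistent or unknown configuration (labels, method tags, endpoints)."""

    category = "config"


class InsufficientDataError(LemsurvError):
    """Too few usable points to fit the linear-quadratic model."""

    category = "insufficient-data"


class NoDataError(LemsurvError):
    """An input table contained no usable rows."""

    category = "no-data"


class DataError(LemsurvError):
    """Malformed values in an input table (reported with row context)."""

    category = "data"


class SchemaError(LemsurvError):
    """Missing columns or an unsupported file schema version."""

    category = "schema"


class AlignmentError(LemsurvError):
    """Predictions and measurements do not share the same dose grid."""

    category = "alignment"


class DoseRangeWarning(UserWarning):
    """Dose outside the 1-6 Gy validity range of the linear-quadratic model."""


class CoefficientClampWarning(UserWarning):
    """An interpolated coefficient would be negative and was clamped to zero."""


class ExtrapolationWarning(UserWarning):
    """Concentration outside [0, C0] evaluated under the extrapolation flag."""
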