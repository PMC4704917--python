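"""Exception hierarchy.

Every error raised by this package derives from :class:`DietvalError`, so
callers (and the CLI) can distinguish domain failures from programming
errors.  Schema problems, missing data and insufficient data map onto the
CLI exit codes 3 and 4.
"""


class DietvalError(Exception):
    """Base class for all dietval errors."""


class SchemaError(DietvalError):
    """A file or table does not conform to the documented schema."""


class DuplicateKeyError(SchemaError):
    """A supposedly unique identifier occurs more than once."""


class UnknownFoodError(DietvalError, KeyError):
    """A food id is not present in the database."""


class UnknownUnitError(DietvalError, KeyError):
    """A portion unit is not defined for the food in question."""


class MissingDataError(DietvalError):
    """An operation that requires complete data met a missing value."""


class ImputationError(DietvalError):
    """An imputation rule could not be applied (e.g. no donors for a median)."""


class InsufficientDataError(DietvalError):
    """Too few observations to compute the requested statistic."""


class AgeRangeError(DietvalError):
    """An age falls outside the coverage of a reference/coefficient table."""


class UndefinedStatisticError(DietvalError):
    """The requested statistic is undefined for this input (e.g. zero variance)."""


class PairingError(DietvalError):
    """Paired inputs could not be matched one-to-one."""


class SingularityError(DietvalError):
    """A regression design matrix is rank deficient."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns or [])


class GenerationError(DietvalError):
    """The synthetic-data generator hit an infeasible configuration."""
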