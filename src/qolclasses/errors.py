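"""Exception hierarchy shared across the package."""


class QolClassesError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(QolClassesError):
    """Input table does not match the expected column schema."""


class RangeError(QolClassesError):
    """An observed value falls outside its item's category range."""


class ConfigError(QolClassesError):
    """A configuration file is malformed or violates an invariant."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class EmptyDataError(QolClassesError):
    """An operation was left with no rows to work on."""


class DegenerateItemError(QolClassesError):
    """An ordinal variable has fewer than two observed categories."""


class EstimationError(QolClassesError):
    """An iterative estimator failed; carries the last iterate if known."""

    def __init__(self, message: str, last_iterate=None):
        self.last_iterate = last_iterate
        super().__init__(message)


class ConvergenceError(EstimationError):
    """No restart of an iterative fit converged."""


class UndefinedStatisticError(QolClassesError):
    """A statistic (e.g. Cronbach's alpha with zero variance) is undefined."""


class RankDeficiencyError(QolClassesError):
    """A regression design matrix is rank deficient."""

    def __init__(self, aliased_columns):
        self.aliased_columns = list(aliased_columns)
        super().__init__(
            "design matrix is rank deficient; aliased columns: "
            + ", ".join(map(str, self.aliased_columns))
        )
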