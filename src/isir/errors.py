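"""Exception hierarchy for cohort validation and scoring."""


class IsirError(Exception):
    """Base class for all package errors."""


class FormatError(IsirError):
    """A file is structurally malformed (missing columns, empty table)."""


class ValidationError(IsirError):
    """A value violates its variable specification or a record invariant."""


class UndefinedScoreError(IsirError):
    """The risk score cannot be formed (empty protective set or zero denominator)."""


class UndefinedStatisticError(IsirError):
    """A statistic is undefined for the given input (constant vector, no events)."""


class ConvergenceError(IsirError):
    """Partial-likelihood maximisation failed to converge."""


class CalibrationError(IsirError):
    """A target rank correlation is unattainable for the given ordinal margins."""
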