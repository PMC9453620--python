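"""Exception hierarchy for circphen."""


class CircphenError(Exception):
    """Base class for all circphen errors."""


class ConfigError(CircphenError, ValueError):
    """An invalid cohort-configuration field.

    Parameters
    ----------
    field : str
        Name of the offending configuration field.
    message : str
        Human-readable description of the constraint violated.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid config field {field!r}: {message}")


class CalibrationError(CircphenError, ValueError):
    """Melatonin threshold calibration could not be performed."""


class DegenerateInputError(CircphenError, ValueError):
    """Input with no usable variance (constant series, collinear covariate...)."""


class SingularDesignError(CircphenError, ValueError):
    """Unpenalized regression on a rank-deficient design."""


class UndefinedPhaseError(CircphenError, ValueError):
    """Predicted circular coordinates are (0, 0); phase is undefined."""


class MissingGeneError(CircphenError, KeyError):
    """A sample lacks genes required by the clock model."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"sample is missing model genes: {', '.join(self.missing)}")
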