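"""Exception hierarchy for climcox."""


class ClimcoxError(Exception):
    """Base class for all climcox errors."""


class ConfigurationError(ClimcoxError):
    """A simulation or pipeline configuration field is invalid."""


class SchemaError(ClimcoxError):
    """An input table is missing required columns or has bad values."""


class BurnInError(ClimcoxError):
    """Insufficient climate history before an individual's entry or
    before the first requested output day of a weighted series."""


class MissingCovariateError(ClimcoxError):
    """A required at-risk day has no covariate value available."""


class DegenerateWindowError(ClimcoxError):
    """All raw lag weights are zero (or non-finite) for a window."""


class WindowParameterError(ClimcoxError):
    """Invalid Weibull window parameters (non-positive shape/scale...)."""


class RankDeficiencyError(ClimcoxError):
    """Design matrix is rank-deficient; carries the aliased term names."""

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(f"design matrix rank-deficient; aliased terms: {self.aliased}")


class ConvergenceError(ClimcoxError):
    """Newton-Raphson failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        self.trace = trace or []
        super().__init__(message)


class DataError(ClimcoxError):
    """Interval data violates a structural requirement (empty risk set...)."""


class UnsupportedLatitudeError(ClimcoxError):
    """Latitude outside the validity range of the daylength formula."""
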