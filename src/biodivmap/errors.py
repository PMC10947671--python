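"""Exception hierarchy used across the pipeline.

Stage code raises the most specific subclass; the CLI maps the three broad
branches (configuration / data / numerical) to distinct exit codes.
"""


class BiodivmapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BiodivmapError):
    """Invalid configuration value (non-positive grid dims, bad thresholds...)."""


class SchemaError(BiodivmapError):
    """Input table is missing required columns or has malformed values."""


class InsufficientDataError(BiodivmapError):
    """Too little data for an estimator (e.g. T < 2 sampling units)."""


class UnattainableCoverageError(BiodivmapError):
    """Requested coverage exceeds the attainable asymptotic coverage."""


class ScreeningError(BiodivmapError):
    """Covariate screening left no usable predictor."""


class FitError(BiodivmapError):
    """A model fit failed to converge or was rejected."""


class VariogramError(BiodivmapError):
    """No variogram family could be fitted to the empirical bins."""


class KrigingError(BiodivmapError):
    """The kriging system is singular even after a jitter retry."""


class GeometryError(BiodivmapError):
    """Degenerate or invalid geometry (coincident points, bad polygons...)."""


class CompositionError(BiodivmapError):
    """Final-map composition found a cell with neither observation nor prediction."""


class NumericalContractError(BiodivmapError):
    """A numerical precondition was violated (e.g. negative variance input)."""
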