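"""Exception hierarchy for the climate-analog pipeline.

Every failure mode the pipeline can hit maps to a distinct exception so
callers (and the per-city quarantine in :mod:`.pipeline`) can react by type.
"""


class AnalogError(Exception):
    """Base class for all package errors."""


class GeometryError(AnalogError):
    """Grids or layers do not share geometry (shape, coordinates, spacing)."""


class ConfigurationError(AnalogError):
    """A variable map, month set, or run configuration is incomplete or inconsistent."""


class DomainError(AnalogError):
    """A spatial domain operation produced an empty or unusable result."""


class CoverageError(AnalogError):
    """A city does not intersect any valid grid cell."""


class InsufficientDataError(AnalogError):
    """Too few stations or years to proceed; the city is excluded, not the run."""


class SingularityError(AnalogError):
    """The ICV covariance is rank deficient; truncation or jitter is required."""
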