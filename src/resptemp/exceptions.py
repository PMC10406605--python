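"""Exception hierarchy for resptemp.

All exceptions derive from :class:`RespTempError` (and from ``ValueError``,
so callers who do not care about the distinction can catch the builtin).
"""


class RespTempError(ValueError):
    """Base class for all resptemp errors."""


class ConfigurationError(RespTempError):
    """Invalid world or run configuration (bad extent, overlapping biomes, ...)."""


class GridMismatchError(RespTempError):
    """A flux field does not match the grid a footprint operator refers to."""


class DomainError(RespTempError):
    """A physical input outside its domain of validity (e.g. T <= 0 K)."""


class ParameterError(RespTempError):
    """A parameter outside its admissible range (e.g. alpha <= 0)."""


class SingularFitError(RespTempError):
    """Regression input is degenerate (too few points, no temperature spread)."""


class UndefinedR2Error(RespTempError):
    """Explanatory power requested for a zero-variance signal."""


class CoverageError(RespTempError):
    """No footprint sensitivity to the requested flux domain."""


class NoOptimumError(RespTempError):
    """Ensemble regression line too flat to locate a zero-adjustment crossing."""


class DegenerateFieldError(RespTempError):
    """A field operation hit a degenerate state (e.g. zero mean respiration)."""
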