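"""Exception hierarchy for spatscale."""


class SpatscaleError(Exception):
    """Base class for all spatscale errors."""


class InvalidParameterError(SpatscaleError, ValueError):
    """An argument violates a precondition (non-positive length, bad range, ...)."""


class RankDeficiencyError(SpatscaleError):
    """The spline design matrix is numerically rank deficient.

    Raised for collinear or otherwise degenerate point geometry; the message
    names the offending columns.
    """


class BandwidthUndefinedError(SpatscaleError):
    """No (or too few) smoothing weights go negative, so the bandwidth is undefined."""


class SpanTooSmallError(SpatscaleError, ValueError):
    """The loess span leaves too few points for a local quadratic fit."""


class MissingDependencyError(SpatscaleError, ImportError):
    """An optional geodata dependency (pyproj, geopandas) is not installed."""
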