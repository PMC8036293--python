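"""Exception hierarchy for the kerato3d pipeline.

Every stage raises a subclass of :class:`Kerato3dError`, so batch drivers can
catch one type, record the failing stage, and keep going.
"""


class Kerato3dError(Exception):
    """Base class for all kerato3d errors."""


class GeometryError(Kerato3dError):
    """A geometric precondition is violated (circle outside frame,
    triangle inequality broken, apex inside the chord circle, ...)."""


class ConfigurationError(Kerato3dError):
    """Inconsistent or impossible configuration (overlapping stage ranges,
    network input too small for the pooling cascade, ...)."""


class NoCircleFound(Kerato3dError):
    """The Hough accumulator has no peak with sufficient support."""


class SegmentationError(Kerato3dError):
    """No usable corneal contour could be extracted from the lateral view."""


class DegenerateChordError(GeometryError):
    """The two limbus chord endpoints coincide."""


class InsufficientMatchesError(Kerato3dError):
    """Not enough cross-view correspondences to estimate the transform."""


class DegenerateSurfaceError(Kerato3dError):
    """All fused points are coplanar; no surface can be rasterized."""


class UndefinedMetricError(Kerato3dError):
    """A classification metric has a zero denominator."""
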