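"""Exception hierarchy shared across the package.

The CLI maps these onto distinct process exit codes so that batch
drivers can tell a bad capture geometry apart from a failed
segmentation or a missing calibration model.
"""


class FoodScaleError(Exception):
    """Base class for all errors raised by foodscale."""


class InvalidSpecError(FoodScaleError):
    """A camera/sensor specification is incomplete or self-inconsistent."""


class GeometryError(FoodScaleError):
    """Capture geometry cannot form a real image (object at or inside
    the focal plane, or a non-positive distance/focal length)."""


class SegmentationError(FoodScaleError):
    """Image segmentation failed in a way that is an error rather than a
    legitimate not-found result (e.g. a region box outside the image)."""


class ModelError(FoodScaleError):
    """Calibration model fitting or lookup failed (too few records,
    degenerate design, unknown trait class)."""


class StatsError(FoodScaleError):
    """A validation statistic is undefined for the given input
    (zero variance, too few observations)."""
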