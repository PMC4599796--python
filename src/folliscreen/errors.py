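"""Exception hierarchy for the screening pipeline.

Every failure mode a batch run must survive (and log) gets its own class so
callers can distinguish "this well is unusable" from "this run is
misconfigured".
"""


class FolliscreenError(Exception):
    """Base class for all package errors."""


class ConfigError(FolliscreenError):
    """Invalid run configuration or plate layout."""


class SegmentationError(FolliscreenError):
    """Base class for per-image analysis failures."""


class DegenerateImageError(SegmentationError):
    """Image histogram has no separable classes (e.g. constant image)."""


class UnevenIlluminationError(SegmentationError):
    """Background unevenness exceeds the configured tolerance.

    Automatic thresholding presumes an evenly exposed background; refusing
    is safer than silently flat-fielding.
    """


class BeadNotFoundError(SegmentationError):
    """No bead/background contrast detected."""


class MultipleBeadsError(SegmentationError):
    """More than one bead occupies the frame."""


class BeadClippedError(SegmentationError):
    """Bead extends beyond the image frame."""


class FollicleNotFoundError(SegmentationError):
    """No candidate follicle component could be located."""


class GeometryError(SegmentationError):
    """Bead/follicle/mask geometries are mutually inconsistent."""


class InsufficientControlsError(FolliscreenError):
    """Fewer than two usable control measurements for cutoff fitting."""
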