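"""Exception hierarchy for the iansegmap pipeline.

Every failure mode that callers are expected to catch has its own class so
that per-record failures can be logged and excluded without masking bugs.
"""


class IansegmapError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(IansegmapError, ValueError):
    """Invalid phantom / pipeline parameters; message names the violated invariant."""


class LandmarkError(IansegmapError, ValueError):
    """A landmark is inconsistent with the image it annotates."""


class GeometryError(IansegmapError, ValueError):
    """Degenerate geometric construction (e.g. empty midline chord)."""


class ShapeError(IansegmapError, ValueError):
    """Arrays that must share a grid do not."""


class SegmentationError(IansegmapError, RuntimeError):
    """Region extraction failed (no component at seed, insufficient contrast)."""


class LeakageError(SegmentationError):
    """Region growing flooded more than the allowed fraction of the volume."""


class ModalityError(IansegmapError, ValueError):
    """An operation was requested on a modality that cannot support it."""


class SiteError(IansegmapError, ValueError):
    """Empty cross-section at the requested measurement site."""


class DataError(IansegmapError, ValueError):
    """Invalid measurement data (e.g. non-positive nerve diameter)."""


class InputError(IansegmapError, ValueError):
    """Empty or unusable input collection."""


class MetadataError(IansegmapError, ValueError):
    """An image file lacks required metadata such as voxel spacing."""


class PipelineError(IansegmapError, RuntimeError):
    """End-to-end run produced zero usable records."""
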