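"""Exception hierarchy for the ossimetry pipeline.

Errors are split by contract: input/format problems (user-fixable), geometric
degeneracies (case-specific, often mirror the manual exclusion of bad
segmentations), and internal topology failures.
"""


class OssimetryError(Exception):
    """Base class for all package errors."""


class VolumeFormatError(OssimetryError):
    """The volume file is readable but violates the label-volume contract
    (non-integer voxels, missing spacing, ...)."""


class ResolutionError(OssimetryError):
    """Voxel spacing is too coarse for the requested geometry."""


class PlacementError(OssimetryError):
    """Phantom solids overlap beyond the contact tolerance."""


class LandmarkNotFoundError(OssimetryError):
    """A required anatomical landmark could not be detected.

    Carries ``landmark`` naming the missing point (e.g. ``"B"``). Mirrors the
    clinical workflow where ears with incomplete segmentation are excluded
    rather than silently mis-measured.
    """

    def __init__(self, landmark: str, message: str | None = None):
        self.landmark = landmark
        super().__init__(message or f"landmark {landmark!r} could not be located")


class FootplateNotFoundError(LandmarkNotFoundError):
    """No near-planar vertex cluster usable as the stapes footplate."""

    def __init__(self, message: str | None = None):
        super().__init__("footplate", message or "no planar footplate cluster found")


class TopologyError(OssimetryError):
    """Mesh violates the watertight/orientation contract."""


class DegenerateGeometryError(OssimetryError):
    """Input geometry is degenerate (coplanar points, coincident landmarks, ...)."""


class EmptyInputError(OssimetryError):
    """An operation received an empty mask / region."""
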