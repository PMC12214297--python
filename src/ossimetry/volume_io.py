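"""Label-volume container and NIfTI / MetaImage round-trip.

All downstream geometry works in millimetre physical space. A voxel at index
``(i, j, k)`` has its *center* at ``origin + index * spacing`` with the
internal canonical axis order ``(x, y, z) = (L->R, P->A, I->S)``. Readers pass
the header spacing/origin through unchanged; anisotropic volumes are accepted
with a warning (clinical U-HRCT inputs are isotropic 0.1 mm).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import VolumeFormatError

log = logging.getLogger(__name__)

#: max/min spacing ratio below which a volume counts as isotropic
ISOTROPY_TOLERANCE = 1.01

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


@dataclass
class LabelVolume:
    """3D integer label grid with physical geometry metadata.

    ``data`` is indexed ``(x, y, z)``; ``spacing`` and ``origin`` are in mm.
    Label 0 is background.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"expected a 3D grid, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.issubdtype(self.data.dtype, np.floating) and np.all(
                self.data == np.round(self.data)
            ):
                self.data = self.data.astype(np.int32)
            else:
                raise VolumeFormatError("label volume voxels must be integers")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be 3 positive floats, got {self.spacing}")
        if np.any(self.data < 0):
            raise VolumeFormatError("labels must be non-negative integers")
        if not self.is_isotropic:
            warnings.warn(
                f"anisotropic spacing {self.spacing}; downstream geometry is computed "
                "in mm so results remain valid, but subvoxel accuracy degrades",
                stacklevel=2,
            )

    # -- geometry -----------------------------------------------------------
    @property
    def is_isotropic(self) -> bool:
        return max(self.spacing) / min(self.spacing) <= ISOTROPY_TOLERANCE

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels(self) -> np.ndarray:
        """Sorted array of labels present (including background 0)."""
        return np.unique(self.data)

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (N,3) to mm coordinates (voxel-center)."""
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)


@dataclass(frozen=True)
class OssicleLabelMap:
    """Which integer label encodes which ossicle (default 1/2/3)."""

    malleus_label: int = 1
    incus_label: int = 2
    stapes_label: int = 3

    def __post_init__(self) -> None:
        labels = (self.malleus_label, self.incus_label, self.stapes_label)
        if len(set(labels)) != 3 or 0 in labels:
            raise ValueError(f"ossicle labels must be distinct and nonzero, got {labels}")

    def as_dict(self) -> dict[str, int]:
        return {
            "malleus": self.malleus_label,
            "incus": self.incus_label,
            "stapes": self.stapes_label,
        }


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) label volume.

    Raises ``IOError`` for unreadable files and ``VolumeFormatError`` for
    non-integer voxel data.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # sitk raises RuntimeError on bad files
        raise IOError(f"could not read {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    arr = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))  # -> (x, y, z)
    spacing = tuple(img.GetSpacing())
    origin = tuple(img.GetOrigin())
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    tag = "RAS"
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        tag = "unknown-direction"
        warnings.warn(
            "volume has a non-identity direction matrix; axes are used as stored "
            "and the orientation tag records the fact",
            stacklevel=2,
        )
    if np.issubdtype(arr.dtype, np.floating) and not np.all(arr == np.round(arr)):
        raise VolumeFormatError(f"{path} contains non-integer voxel values")
    vol = LabelVolume(arr, spacing=spacing, origin=origin, axis_orientation=tag)
    if not vol.is_isotropic:
        log.warning("volume %s is anisotropic: spacing=%s", path, spacing)
    return vol


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write the volume; format chosen from the file suffix."""
    path = Path(path)
    if not any(str(path).endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise ValueError(f"unsupported suffix for {path}; use one of {_SUPPORTED_SUFFIXES}")
    data = vol.data
    # NIfTI has no int64 support in some readers; 32-bit is ample for labels.
    if data.dtype not in (np.uint8, np.int16, np.uint16, np.int32):
        data = data.astype(np.int32)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, str(path))


def extract_label_mask(vol: LabelVolume, label: int) -> LabelVolume:
    """Binary mask (0/1) of one label; absent labels yield an empty mask + warning."""
    mask = (vol.data == label).astype(np.uint8)
    if label != 0 and not mask.any():
        warnings.warn(f"label {label} absent from volume; returning empty mask", stacklevel=2)
    return LabelVolume(mask, spacing=vol.spacing, origin=vol.origin,
                       axis_orientation=vol.axis_orientation)
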