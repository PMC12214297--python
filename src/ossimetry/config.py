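"""Run configuration: every tunable of the pipeline in one serializable place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .volume_io import OssicleLabelMap


@dataclass
class RunConfig:
    """Pipeline parameters with their phantom-tuned defaults.

    Geometry is in mm; curvatures in 1/mm (mean) and 1/mm^2 (Gaussian).
    Unknown keys in a YAML config are rejected rather than ignored.
    """

    malleus_label: int = 1
    incus_label: int = 2
    stapes_label: int = 3
    # level-set refinement is off by default: the signed-distance zero
    # crossing of a clean label mask is already subvoxel-accurate, and
    # curvature flow erodes the thin stapes crura; enable for noisy masks
    refine_iterations: int = 0
    refine_fidelity_band_voxels: float = 0.5
    smooth_iterations: int = 20
    smooth_passband: float = 0.4
    min_gauss: float = 4.0
    nms_radius: float = 0.4
    planar_h_threshold: float = 0.5
    plane_rms_threshold: float = 0.08
    footplate_band: float = 0.5
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.refine_iterations < 0 or self.smooth_iterations < 0:
            raise ValueError("iteration counts must be >= 0")
        if not (0.0 < self.smooth_passband < 2.0):
            raise ValueError("smooth_passband must be in (0, 2)")
        for name in ("min_gauss", "nms_radius", "planar_h_threshold",
                     "plane_rms_threshold", "footplate_band",
                     "refine_fidelity_band_voxels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def label_map(self) -> OssicleLabelMap:
        return OssicleLabelMap(self.malleus_label, self.incus_label, self.stapes_label)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Short stable hash embedded in output provenance blocks."""
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config": self.as_dict(), "config_hash": self.digest()}
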