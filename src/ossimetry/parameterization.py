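"""Map detected landmarks to the 12 reported ossicular-chain parameters.

Eight landmark distances (mm), the incudostapedial joint angle (degrees) and
three per-ossicle mesh volumes (mm^3). Stapes-dependent fields (GI, HJ, the
joint angle and the stapes volume) degrade gracefully to "unavailable" when
stapes landmark detection fails — mirroring clinical practice where the
malleus and incus segment reliably but the stapes often does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import geometry_features as gf
from . import surface_reconstruction as sr
from .errors import (
    DegenerateGeometryError,
    EmptyInputError,
    OssimetryError,
)
from .volume_io import LabelVolume, OssicleLabelMap, extract_label_mask

log = logging.getLogger(__name__)

DISTANCE_PARAMETERS = (
    "malleus_total_height_AC",
    "malleus_manubrium_BC",
    "malleus_head_neck_AB",
    "incus_total_height_DG",
    "incus_total_width_EF",
    "incus_process_distance_FG",
    "stapes_total_height_GI",
    "stapes_footplate_HJ",
)
VOLUME_PARAMETERS = ("malleus_volume", "incus_volume", "stapes_volume")
ANGLE_PARAMETER = "incudostapedial_angle_DGI"
ALL_PARAMETERS = DISTANCE_PARAMETERS + (ANGLE_PARAMETER,) + VOLUME_PARAMETERS
STAPES_DEPENDENT = (
    "stapes_total_height_GI",
    "stapes_footplate_HJ",
    ANGLE_PARAMETER,
    "stapes_volume",
)


def distance(p: np.ndarray, q: np.ndarray) -> float:
    """Euclidean distance in mm."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("landmark coordinates must be finite")
    return float(np.linalg.norm(p - q))


def joint_angle(d: np.ndarray, g: np.ndarray, i: np.ndarray) -> float:
    """Angle at vertex G between rays G->D and G->I, in degrees.

    Computed with atan2(|u x v|, u.v) which is numerically stable for both
    near-0 and near-180 degree configurations.
    """
    d, g, i = (np.asarray(x, dtype=float) for x in (d, g, i))
    u, v = d - g, i - g
    if np.linalg.norm(u) < 1e-12 or np.linalg.norm(v) < 1e-12:
        raise DegenerateGeometryError("joint angle undefined: coincident landmarks")
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), float(u @ v))))


@dataclass
class OssicleMeasurements:
    """The 12 parameters; ``available`` flags mark fields that were measured."""

    values: dict[str, float] = field(default_factory=dict)
    available: dict[str, bool] = field(default_factory=dict)

    def set(self, name: str, value: float) -> None:
        if name not in ALL_PARAMETERS:
            raise KeyError(f"unknown parameter {name}")
        self.values[name] = float(value)
        self.available[name] = True

    def mark_unavailable(self, name: str) -> None:
        self.available[name] = False
        self.values.pop(name, None)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def is_available(self, name: str) -> bool:
        return self.available.get(name, False)

    def validate(self) -> None:
        for name in DISTANCE_PARAMETERS + VOLUME_PARAMETERS:
            if self.is_available(name) and self.values[name] <= 0:
                raise ValueError(f"{name} must be positive, got {self.values[name]}")
        if self.is_available(ANGLE_PARAMETER):
            ang = self.values[ANGLE_PARAMETER]
            if not (0.0 < ang < 180.0):
                raise ValueError(f"joint angle {ang} outside (0, 180)")
        if all(self.is_available(k) for k in
               ("malleus_total_height_AC", "malleus_manubrium_BC", "malleus_head_neck_AB")):
            ac = self.values["malleus_total_height_AC"]
            if ac + 1e-9 < max(self.values["malleus_manubrium_BC"],
                               self.values["malleus_head_neck_AB"]):
                raise ValueError("AC must be the malleus maximum distance")

    def as_dict(self) -> dict[str, float | None]:
        return {k: (self.values[k] if self.is_available(k) else None)
                for k in ALL_PARAMETERS}


@dataclass
class QCReport:
    warnings: list[str] = field(default_factory=list)
    mesh_stats: dict[str, dict] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    voxel_volumes: dict[str, float] = field(default_factory=dict)
    landmarks_mm: dict[str, list[float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "warnings": self.warnings,
            "mesh_stats": self.mesh_stats,
            "provenance": self.provenance,
            "voxel_volumes": self.voxel_volumes,
            "landmarks_mm": self.landmarks_mm,
        }


def _reconstruct(mask: LabelVolume, cfg, qc: QCReport, name: str):
    cleaned, discarded = sr.largest_connected_component(mask.data)
    if discarded:
        qc.warnings.append(f"{name}: discarded {discarded} disconnected island(s)")
    mask = LabelVolume(cleaned.astype(np.uint8), mask.spacing, mask.origin,
                       mask.axis_orientation)
    qc.voxel_volumes[name] = float(cleaned.sum()) * mask.voxel_volume
    mesh = sr.mask_to_mesh(
        mask,
        refine_iterations=cfg.refine_iterations,
        fidelity_band_voxels=cfg.refine_fidelity_band_voxels,
        smooth_iterations=cfg.smooth_iterations,
        smooth_passband=cfg.smooth_passband,
    )
    qc.mesh_stats[name] = {
        "n_vertices": len(mesh.vertices),
        "n_faces": len(mesh.faces),
        "watertight": bool(mesh.is_watertight),
        "mesh_volume_mm3": sr.mesh_volume(mesh),
    }
    return mesh


def measure_chain(
    volume: LabelVolume,
    label_map: OssicleLabelMap | None = None,
    config=None,
    mesh_sink: dict | None = None,
) -> tuple[OssicleMeasurements, QCReport]:
    """Run the full pipeline on a labeled chain volume.

    The malleus and incus labels must be present; the stapes is optional and
    its four dependent parameters are flagged unavailable when it is missing
    or its landmarks cannot be found. Pass a dict as ``mesh_sink`` to receive
    the reconstructed per-ossicle meshes (e.g. for PLY/STL export).
    """
    from .config import RunConfig  # local import to avoid a cycle

    label_map = label_map or OssicleLabelMap()
    cfg = config or RunConfig()
    present = set(np.unique(volume.data).tolist())
    for name, lab in (("malleus", label_map.malleus_label),
                      ("incus", label_map.incus_label)):
        if lab not in present:
            raise EmptyInputError(f"required {name} label {lab} absent from volume")

    qc = QCReport()
    meas = OssicleMeasurements()

    malleus_mesh = _reconstruct(extract_label_mask(volume, label_map.malleus_label),
                                cfg, qc, "malleus")
    incus_mesh = _reconstruct(extract_label_mask(volume, label_map.incus_label),
                              cfg, qc, "incus")
    stapes_mesh = None
    if label_map.stapes_label in present:
        try:
            stapes_mesh = _reconstruct(extract_label_mask(volume, label_map.stapes_label),
                                       cfg, qc, "stapes")
        except (OssimetryError, ValueError) as exc:
            qc.warnings.append(f"stapes reconstruction failed: {exc}")
    else:
        qc.warnings.append("stapes label absent; stapes parameters unavailable")

    if mesh_sink is not None:
        for name, mesh in (("malleus", malleus_mesh), ("incus", incus_mesh),
                           ("stapes", stapes_mesh)):
            if mesh is not None:
                mesh_sink[name] = mesh

    # malleus
    m_fps = gf.locate_malleus_landmarks(
        malleus_mesh, min_gauss=cfg.min_gauss, nms_radius=cfg.nms_radius
    )
    qc.warnings.extend(m_fps.warnings)
    qc.provenance.update({f"malleus.{k}": v for k, v in m_fps.provenance.items()})
    qc.landmarks_mm.update({f"malleus.{k}": v.tolist() for k, v in m_fps.points.items()})
    meas.set("malleus_total_height_AC", distance(m_fps["A"], m_fps["C"]))
    meas.set("malleus_manubrium_BC", distance(m_fps["B"], m_fps["C"]))
    meas.set("malleus_head_neck_AB", distance(m_fps["A"], m_fps["B"]))
    meas.set("malleus_volume", sr.mesh_volume(malleus_mesh))

    # incus (uses the stapes mesh, when present, to orient D vs G)
    stapes_pts = np.asarray(stapes_mesh.vertices) if stapes_mesh is not None else None
    i_fps = gf.locate_incus_landmarks(
        incus_mesh, stapes_points=stapes_pts,
        min_gauss=cfg.min_gauss, nms_radius=cfg.nms_radius,
    )
    qc.warnings.extend(i_fps.warnings)
    qc.provenance.update({f"incus.{k}": v for k, v in i_fps.provenance.items()})
    qc.landmarks_mm.update({f"incus.{k}": v.tolist() for k, v in i_fps.points.items()})
    meas.set("incus_total_height_DG", distance(i_fps["D"], i_fps["G"]))
    meas.set("incus_total_width_EF", distance(i_fps["E"], i_fps["F"]))
    meas.set("incus_process_distance_FG", distance(i_fps["F"], i_fps["G"]))
    meas.set("incus_volume", sr.mesh_volume(incus_mesh))

    # stapes + joint angle
    s_fps = None
    if stapes_mesh is not None:
        try:
            s_fps = gf.locate_stapes_landmarks(
                stapes_mesh, incus_g=i_fps["G"],
                planar_h_threshold=cfg.planar_h_threshold,
                plane_rms_threshold=cfg.plane_rms_threshold,
                footplate_band=cfg.footplate_band,
            )
        except (OssimetryError, ValueError) as exc:
            qc.warnings.append(f"stapes landmarks failed: {exc}")
    if s_fps is not None:
        qc.warnings.extend(s_fps.warnings)
        qc.provenance.update({f"stapes.{k}": v for k, v in s_fps.provenance.items()})
        qc.landmarks_mm.update({f"stapes.{k}": v.tolist() for k, v in s_fps.points.items()})
        meas.set("stapes_total_height_GI", distance(s_fps["G_s"], s_fps["I"]))
        meas.set("stapes_footplate_HJ", distance(s_fps["H"], s_fps["J"]))
        meas.set(ANGLE_PARAMETER, joint_angle(i_fps["D"], i_fps["G"], s_fps["I"]))
        meas.set("stapes_volume", sr.mesh_volume(stapes_mesh))
    else:
        for name in STAPES_DEPENDENT:
            meas.mark_unavailable(name)
    meas.validate()
    return meas, qc
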