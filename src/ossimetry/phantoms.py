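"""Parametric voxel phantoms of the three ossicles with analytic ground truth.

The phantoms are unions of spheres, capsules and an elliptical plate, arranged
so that every reported measurement parameter — the eight landmark distances,
the incudostapedial joint angle and the three volumes — has a closed-form
(or, for volumes, exactly-corrected) ground truth. The generators are
parameterized directly by the target anatomical distances; internal solids
are solved from them, so the stored ground truth equals the requested targets
exactly.

Default dimensions follow the automated population means of the clinical
study conditions the package models: malleus AC/BC/AB = 7.91/4.36/4.89 mm,
incus DG/EF/FG = 6.56/4.97/5.55 mm, stapes GI/HJ = 3.25/2.63 mm and an
incudostapedial angle of 96.83 degrees, at 0.1 mm isotropic voxels.

Landmark letters (shared with the measurement side):
  A head apex, B lateral-process tip, C manubrium tip   (malleus)
  D body top, E body point farthest from F, F short-process tip,
  G long-process tip                                     (incus)
  G_s head apex, H/J footplate major-axis endpoints,
  I footplate bottom point farthest from the head        (stapes)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from ._solids import (
    Capsule,
    EllipticPlate,
    Sphere,
    cross_overlap_volume,
    union_contains,
    union_volume,
)
from .errors import (
    DegenerateGeometryError,
    LandmarkNotFoundError,
    PlacementError,
    ResolutionError,
)
from .volume_io import LabelVolume, OssicleLabelMap

DEFAULT_SPACING = 0.1  # mm, the U-HRCT voxel size the pipeline targets
_RASTER_MARGIN = 0.45  # mm of background padding around the solids
_OVERLAP_GRID = 0.02  # mm, quadrature grid for volume overlap corrections


@dataclass(frozen=True)
class RigidPose:
    """Rotation (applied first) followed by translation, in mm."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-9) or np.linalg.det(rot) < 0:
            raise ValueError("pose rotation must be a proper rotation matrix")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))

    @classmethod
    def random(cls, rng: np.random.Generator, max_translation: float = 0.5) -> "RigidPose":
        return cls(Rotation.random(random_state=rng).as_matrix(),
                   rng.uniform(-max_translation, max_translation, 3))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.einsum("ij,...j->...i", self.rotation, pts) + self.translation

    def compose(self, other: "RigidPose") -> "RigidPose":
        """self after other: x -> self(other(x))."""
        return RigidPose(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)


@dataclass(frozen=True)
class MalleusPhantomSpec:
    """Bent hammer: head sphere, neck capsule, manubrium capsule, lateral bump."""

    total_height: float = 7.91      # AC, mm
    manubrium_length: float = 4.36  # BC, mm
    head_neck_length: float = 4.89  # AB, mm
    head_radius: float = 1.1
    neck_radius: float = 0.4
    manubrium_radius: float = 0.3
    bump_radius: float = 0.28       # lateral-process bump; 0 removes landmark B
    pose: RigidPose = field(default_factory=RigidPose)

    def __post_init__(self):
        for name in ("total_height", "manubrium_length", "head_neck_length",
                     "head_radius", "neck_radius", "manubrium_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bump_radius < 0:
            raise ValueError("bump_radius must be >= 0")


@dataclass(frozen=True)
class IncusPhantomSpec:
    """Anvil: body sphere with long and short process capsules."""

    total_height: float = 6.56       # DG, mm
    total_width: float = 4.97        # EF, mm
    process_distance: float = 5.55   # FG, mm
    body_radius: float = 1.3
    long_process_radius: float = 0.3
    short_process_radius: float = 0.3
    pose: RigidPose = field(default_factory=RigidPose)

    def __post_init__(self):
        for name in ("total_height", "total_width", "process_distance",
                     "body_radius", "long_process_radius", "short_process_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class StapesPhantomSpec:
    """Stirrup: head sphere, two crura capsules, elliptical footplate."""

    total_height: float = 3.25       # GI, mm
    footplate_length: float = 2.63   # HJ = 2a, mm
    footplate_minor_semiaxis: float = 0.65
    footplate_thickness: float = 0.3
    footplate_tilt_deg: float = 0.0  # rotation of the plate about its minor axis
    perforation_radius: float = 0.0  # 0 = intact footplate
    head_radius: float = 0.4
    head_offset: float = 0.2         # lateral head shift; makes landmark I unique
    crura_radius: float = 0.22
    pose: RigidPose = field(default_factory=RigidPose)

    def __post_init__(self):
        if self.footplate_length / 2.0 <= self.footplate_minor_semiaxis:
            raise ValueError("footplate major semi-axis must exceed the minor one")
        for name in ("total_height", "footplate_minor_semiaxis", "footplate_thickness",
                     "head_radius", "crura_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.perforation_radius < 0:
            raise ValueError("perforation_radius must be >= 0")
        if self.perforation_radius >= self.footplate_minor_semiaxis:
            raise ValueError("perforation must lie strictly inside the footplate")


@dataclass
class PhantomGroundTruth:
    """Analytic landmarks (mm) and the measurement parameters they imply."""

    landmarks: dict[str, np.ndarray]
    parameters: dict[str, float]

    def transformed(self, pose: RigidPose) -> "PhantomGroundTruth":
        return PhantomGroundTruth(
            {k: pose.apply(v) for k, v in self.landmarks.items()},
            dict(self.parameters),
        )

    def check_self_consistent(self, atol: float = 1e-9) -> None:
        """Stored distances must equal the distances between stored landmarks."""
        pairs = {
            "malleus_total_height_AC": ("A", "C"),
            "malleus_manubrium_BC": ("B", "C"),
            "malleus_head_neck_AB": ("A", "B"),
            "incus_total_height_DG": ("D", "G"),
            "incus_total_width_EF": ("E", "F"),
            "incus_process_distance_FG": ("F", "G"),
            "stapes_total_height_GI": ("G_s", "I"),
            "stapes_footplate_HJ": ("H", "J"),
        }
        for param, (p, q) in pairs.items():
            if param in self.parameters and p in self.landmarks and q in self.landmarks:
                d = float(np.linalg.norm(self.landmarks[p] - self.landmarks[q]))
                if abs(d - self.parameters[param]) > atol:
                    raise AssertionError(
                        f"{param}: stored {self.parameters[param]} vs landmarks {d}"
                    )
        if "incudostapedial_angle_DGI" in self.parameters:
            d, g, i = (self.landmarks[k] for k in ("D", "G", "I"))
            u, v = d - g, i - g
            ang = np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), u @ v))
            if abs(ang - self.parameters["incudostapedial_angle_DGI"]) > 1e-6:
                raise AssertionError("stored joint angle inconsistent with landmarks")


# ---------------------------------------------------------------------------
# canonical constructions
# ---------------------------------------------------------------------------

def _solve_triangle_apex(ac: float, bc: float, ab: float) -> np.ndarray:
    """Position of B in the canonical frame with C=(0,0,0), A=(0,0,ac)."""
    z_b = (ac**2 + bc**2 - ab**2) / (2.0 * ac)
    x_sq = bc**2 - z_b**2
    if x_sq <= 0.01 or not (0.0 < z_b < ac):
        raise DegenerateGeometryError(
            f"distance targets AC={ac}, BC={bc}, AB={ab} do not form a usable bent shape"
        )
    return np.array([np.sqrt(x_sq), 0.0, z_b])


def _malleus_canonical(spec: MalleusPhantomSpec):
    ac, bc, ab = spec.total_height, spec.manubrium_length, spec.head_neck_length
    a_pt = np.array([0.0, 0.0, ac])
    c_pt = np.zeros(3)
    if spec.bump_radius <= 0:
        raise LandmarkNotFoundError(
            "B", "lateral-process bump removed: landmark B is unavailable"
        )
    b_pt = _solve_triangle_apex(ac, bc, ab)
    head_center = np.array([0.0, 0.0, ac - spec.head_radius])
    tip_anchor = np.array([0.0, 0.0, spec.manubrium_radius])  # manubrium cap apex = C
    # Iterate the elbow position so the bump protrudes along the local outward
    # bisector of the bend; then the bump apex is exactly B.
    d_hat = np.array([1.0, 0.0, 0.0])
    elbow = b_pt - (spec.neck_radius + spec.bump_radius) * d_hat
    for _ in range(60):
        out = -(_unit(head_center - elbow) + _unit(tip_anchor - elbow))
        nrm = np.linalg.norm(out)
        if nrm < 1e-12:
            raise DegenerateGeometryError("malleus neck and manubrium are collinear")
        d_new = out / nrm
        elbow_new = b_pt - (spec.neck_radius + spec.bump_radius) * d_new
        if np.linalg.norm(elbow_new - elbow) < 1e-13:
            elbow, d_hat = elbow_new, d_new
            break
        elbow, d_hat = elbow_new, d_new
    bump_center = b_pt - spec.bump_radius * d_hat
    prims = [
        Sphere(head_center, spec.head_radius),
        Capsule(head_center, elbow, spec.neck_radius),
        Capsule(elbow, tip_anchor, spec.manubrium_radius),
        Sphere(bump_center, spec.bump_radius),
    ]
    _check_extreme_pair(prims, expected=ac, label="malleus AC")
    landmarks = {"A": a_pt, "B": b_pt, "C": c_pt}
    params = {
        "malleus_total_height_AC": ac,
        "malleus_manubrium_BC": bc,
        "malleus_head_neck_AB": ab,
    }
    return prims, landmarks, params


def _incus_canonical(spec: IncusPhantomSpec):
    dg, ef, fg = spec.total_height, spec.total_width, spec.process_distance
    r_b, r_l, r_s = spec.body_radius, spec.long_process_radius, spec.short_process_radius
    g_pt = np.zeros(3)
    d_pt = np.array([0.0, 0.0, dg])
    body_center = np.array([0.0, 0.0, dg - r_b])
    # F solves |F - G| = fg and |body_center - F| = ef - r_body (so that the body
    # point farthest from F, E, sits at distance ef exactly).
    dist_of = ef - r_b
    if dist_of <= r_b:
        raise DegenerateGeometryError("incus width target too small for the body radius")
    z_f = (fg**2 + np.linalg.norm(body_center) ** 2 - dist_of**2) / (2.0 * body_center[2])
    x_sq = fg**2 - z_f**2
    if x_sq <= 0.01:
        raise DegenerateGeometryError(
            f"incus targets DG={dg}, EF={ef}, FG={fg} are not constructible"
        )
    f_pt = np.array([np.sqrt(x_sq), 0.0, z_f])
    e_pt = body_center + r_b * _unit(body_center - f_pt)
    long_end = g_pt + r_l * _unit(body_center - g_pt)  # cap apex lands on G
    short_end = f_pt - r_s * _unit(f_pt - body_center)  # cap apex lands on F
    prims = [
        Sphere(body_center, r_b),
        Capsule(body_center, long_end, r_l),
        Capsule(body_center, short_end, r_s),
    ]
    _check_extreme_pair(prims, expected=dg, label="incus DG")
    landmarks = {"D": d_pt, "E": e_pt, "F": f_pt, "G": g_pt}
    params = {
        "incus_total_height_DG": dg,
        "incus_total_width_EF": ef,
        "incus_process_distance_FG": fg,
    }
    return prims, landmarks, params


def _stapes_canonical(spec: StapesPhantomSpec):
    a = spec.footplate_length / 2.0
    b = spec.footplate_minor_semiaxis
    t = spec.footplate_thickness
    gi = spec.total_height
    reach = a + spec.head_offset
    if gi <= reach:
        raise DegenerateGeometryError("stapes height target too small for the footplate")
    apex_z = np.sqrt(gi**2 - reach**2) - t
    if apex_z <= spec.head_radius:
        raise DegenerateGeometryError("stapes head would intersect the footplate")
    apex = np.array([-spec.head_offset, 0.0, apex_z])
    head_center = apex - np.array([0.0, 0.0, spec.head_radius])
    tilt = Rotation.from_euler("y", spec.footplate_tilt_deg, degrees=True).as_matrix()
    plate_center = np.array([0.0, 0.0, -t / 2.0])
    plate_axes = np.stack([tilt @ np.eye(3)[i] for i in range(3)])  # rows: major/minor/normal
    plate = EllipticPlate(plate_center, plate_axes, a, b, t, spec.perforation_radius)
    # crura drop from the head into the plate top, splayed in +-y
    crura = [
        Capsule(head_center, plate_center + plate_axes.T @ np.array([0.0, sy * 0.55, t * 0.17]),
                spec.crura_radius)
        for sy in (+1.0, -1.0)
    ]
    prims = [Sphere(head_center, spec.head_radius), *crura, plate]
    # landmarks: H/J mid-rim major-axis endpoints, I = bottom-rim point farthest
    # from the head apex (dense rim search; closed form when the plate is flat)
    h_pt = plate_center + plate_axes[0] * (-a)
    j_pt = plate_center + plate_axes[0] * a
    theta = np.linspace(0.0, 2.0 * np.pi, 20001)
    rim = (
        plate_center
        + np.outer(a * np.cos(theta), plate_axes[0])
        + np.outer(b * np.sin(theta), plate_axes[1])
        - (t / 2.0) * plate_axes[2]
    )
    i_pt = rim[np.argmax(np.linalg.norm(rim - apex, axis=1))]
    gi_actual = float(np.linalg.norm(apex - i_pt))
    landmarks = {"G_s": apex, "H": h_pt, "I": i_pt, "J": j_pt}
    params = {
        "stapes_total_height_GI": gi_actual,
        "stapes_footplate_HJ": float(np.linalg.norm(j_pt - h_pt)),
    }
    return prims, landmarks, params


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError("zero-length direction")
    return v / n


def _check_extreme_pair(prims, expected: float, label: str) -> None:
    """The designed landmark pair must be the solid's true diameter."""
    balls = []
    for p in prims:
        if isinstance(p, Sphere):
            balls.append((p.center, p.radius))
        elif isinstance(p, Capsule):
            balls.append((p.p0, p.radius))
            balls.append((p.p1, p.radius))
    best = 0.0
    for i in range(len(balls)):
        for j in range(i, len(balls)):
            d = np.linalg.norm(balls[i][0] - balls[j][0]) + balls[i][1] + balls[j][1]
            best = max(best, d)
    if best > expected + 1e-6:
        raise DegenerateGeometryError(
            f"{label}: construction has a farther point pair ({best:.4f} > {expected:.4f})"
        )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _min_feature_radius(prims) -> float:
    radii = []
    for p in prims:
        if isinstance(p, (Sphere, Capsule)):
            radii.append(p.radius)
        elif isinstance(p, EllipticPlate):
            # a slab of thickness t is resolvable like a tube of radius t:
            # center-inclusion keeps >= t/spacing voxel layers across it
            radii.append(p.thickness)
    return min(radii)


def _check_spacing(prims, spacing: float) -> None:
    r_min = _min_feature_radius(prims)
    if spacing > r_min:
        raise ResolutionError(
            f"spacing {spacing} mm cannot resolve the finest feature radius {r_min:.3f} mm"
        )
    if spacing > r_min / 2.0:
        warnings.warn(
            f"spacing {spacing} mm is coarse for feature radius {r_min:.3f} mm; "
            "expect large discretization error",
            stacklevel=3,
        )


def rasterize_solids(
    labeled_prims: list[tuple[int, list]],
    spacing: float,
    margin: float = _RASTER_MARGIN,
    contact_tolerance_mm3: float = 0.02,
) -> LabelVolume:
    """Voxelize solids by center-inclusion onto a shared grid.

    Earlier entries win contested voxels; a contested volume beyond
    ``contact_tolerance_mm3`` raises ``PlacementError``.
    """
    all_prims = [p for _, prims in labeled_prims for p in prims]
    los, his = zip(*(p.bbox() for p in all_prims))
    lo = np.min(los, axis=0) - margin
    hi = np.max(his, axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    origin = tuple(lo)
    data = np.zeros(shape, dtype=np.int16)
    conflict_voxels = 0
    for label, prims in labeled_prims:
        claimed = np.zeros(shape, dtype=bool)
        for p in prims:
            plo, phi = p.bbox()
            i0 = np.maximum(np.floor((plo - lo) / spacing).astype(int) - 1, 0)
            i1 = np.minimum(np.ceil((phi - lo) / spacing).astype(int) + 2, shape)
            xs = lo[0] + np.arange(i0[0], i1[0]) * spacing
            ys = lo[1] + np.arange(i0[1], i1[1]) * spacing
            zs = lo[2] + np.arange(i0[2], i1[2]) * spacing
            pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
            claimed[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= p.contains(pts)
        contested = claimed & (data != 0)
        conflict_voxels += int(contested.sum())
        data[claimed & (data == 0)] = label
    if conflict_voxels * spacing**3 > contact_tolerance_mm3:
        raise PlacementError(
            f"solids overlap by {conflict_voxels * spacing ** 3:.4f} mm^3 "
            f"(> contact tolerance {contact_tolerance_mm3} mm^3)"
        )
    return LabelVolume(data, spacing=(spacing,) * 3, origin=origin)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def _generate_single(prims, landmarks, params, volume_key, pose, spacing):
    _check_spacing(prims, spacing)
    params = dict(params)
    # volume in the canonical frame: exactly pose-invariant by construction
    params[volume_key] = union_volume(prims, h=_OVERLAP_GRID)
    rot, tr = pose.rotation, pose.translation
    prims = [p.transformed(rot, tr) for p in prims]
    truth = PhantomGroundTruth(
        {k: pose.apply(v) for k, v in landmarks.items()}, params
    )
    vol = rasterize_solids([(1, prims)], spacing)
    return vol, truth, prims


def generate_malleus_phantom(
    spec: MalleusPhantomSpec | None = None,
    spacing: float = DEFAULT_SPACING,
    seed: int = 0,
) -> tuple[LabelVolume, PhantomGroundTruth]:
    spec = spec or MalleusPhantomSpec()
    prims, lms, params = _malleus_canonical(spec)
    vol, truth, _ = _generate_single(prims, lms, params, "malleus_volume", spec.pose, spacing)
    return vol, truth


def generate_incus_phantom(
    spec: IncusPhantomSpec | None = None,
    spacing: float = DEFAULT_SPACING,
    seed: int = 0,
) -> tuple[LabelVolume, PhantomGroundTruth]:
    spec = spec or IncusPhantomSpec()
    prims, lms, params = _incus_canonical(spec)
    vol, truth, _ = _generate_single(prims, lms, params, "incus_volume", spec.pose, spacing)
    return vol, truth


def generate_stapes_phantom(
    spec: StapesPhantomSpec | None = None,
    spacing: float = DEFAULT_SPACING,
    seed: int = 0,
) -> tuple[LabelVolume, PhantomGroundTruth]:
    spec = spec or StapesPhantomSpec()
    prims, lms, params = _stapes_canonical(spec)
    vol, truth, _ = _generate_single(prims, lms, params, "stapes_volume", spec.pose, spacing)
    return vol, truth


#: where the malleus sits relative to the incus in the canonical chain frame
_MALLEUS_CHAIN_OFFSET = np.array([-4.0, 0.0, -0.8])


def generate_chain_phantom(
    malleus_spec: MalleusPhantomSpec | None = None,
    incus_spec: IncusPhantomSpec | None = None,
    stapes_spec: StapesPhantomSpec | None = None,
    joint_angle_deg: float = 96.83,
    spacing: float = DEFAULT_SPACING,
    seed: int = 0,
    label_map: OssicleLabelMap | None = None,
    pose: RigidPose | None = None,
) -> tuple[LabelVolume, PhantomGroundTruth]:
    """Assemble all three ossicles with a prescribed incudostapedial angle.

    The stapes head apex is placed at the incus long-process tip G; the angle
    at G between the rays G->D and G->I equals ``joint_angle_deg`` exactly.
    ``pose`` (default identity) rigidly moves the whole chain.
    """
    if not (0.0 < joint_angle_deg < 180.0):
        raise DegenerateGeometryError(
            f"joint angle {joint_angle_deg} deg is degenerate-collinear or reflex"
        )
    malleus_spec = malleus_spec or MalleusPhantomSpec()
    incus_spec = incus_spec or IncusPhantomSpec()
    stapes_spec = stapes_spec or StapesPhantomSpec()
    label_map = label_map or OssicleLabelMap()
    pose = pose or RigidPose()

    m_prims, m_lms, m_params = _malleus_canonical(malleus_spec)
    i_prims, i_lms, i_params = _incus_canonical(incus_spec)
    s_prims, s_lms, s_params = _stapes_canonical(stapes_spec)

    # malleus: fixed offset beside the incus body
    m_pose = RigidPose(np.eye(3), _MALLEUS_CHAIN_OFFSET)
    # stapes: rotate so that apex->I makes the requested angle with G->D (= +z),
    # then translate the apex onto G (= origin of the incus canonical frame)
    apex, i_pt = s_lms["G_s"], s_lms["I"]
    v_hat = _unit(i_pt - apex)
    theta = np.radians(joint_angle_deg)
    u_hat = np.array([0.0, np.sin(theta), np.cos(theta)])
    # exact primary alignment apex->I onto the joint direction, then a spin
    # about that direction keeping the stapes head axis as upright as
    # possible so the head stays near-tangent to the incus tip
    axis = np.cross(v_hat, u_hat)
    s_norm = np.linalg.norm(axis)
    ang = np.arctan2(s_norm, float(v_hat @ u_hat))
    r1 = (Rotation.from_rotvec(axis / s_norm * ang) if s_norm > 1e-12
          else Rotation.identity()).as_matrix()
    z = np.array([0.0, 0.0, 1.0])
    w = r1 @ z
    w_perp = w - (w @ u_hat) * u_hat
    t_perp = z - (z @ u_hat) * u_hat
    if np.linalg.norm(w_perp) > 1e-12 and np.linalg.norm(t_perp) > 1e-12:
        spin = np.arctan2(float(np.cross(w_perp, t_perp) @ u_hat),
                          float(w_perp @ t_perp))
        rot_s = Rotation.from_rotvec(u_hat * spin).as_matrix() @ r1
    else:
        rot_s = r1
    s_pose = RigidPose(rot_s, i_lms["G"] - rot_s @ apex)

    parts = [
        (label_map.malleus_label, m_prims, m_lms, m_params, m_pose, "malleus_volume"),
        (label_map.incus_label, i_prims, i_lms, i_params, RigidPose(), "incus_volume"),
        (label_map.stapes_label, s_prims, s_lms, s_params, s_pose, "stapes_volume"),
    ]
    labeled_prims = []
    landmarks: dict[str, np.ndarray] = {}
    params: dict[str, float] = {}
    placed: dict[str, list] = {}
    for label, prims, lms, pars, part_pose, vol_key in parts:
        # volumes are computed in the assembly frame, before the whole-chain
        # pose, so the recorded ground truth is exactly pose-invariant
        params.update(pars)
        params[vol_key] = union_volume(prims, h=_OVERLAP_GRID)
        assembled = [p.transformed(part_pose.rotation, part_pose.translation)
                     for p in prims]
        placed[vol_key] = assembled
        chain_pose = pose.compose(part_pose)
        labeled_prims.append((label, [p.transformed(pose.rotation, pose.translation)
                                      for p in assembled]))
        landmarks.update({k: chain_pose.apply(v) for k, v in lms.items()})
    # the stapes head is tangent to the incus tip: contested voxels go to the
    # incus, so the stapes ground-truth volume excludes the contact lens
    lens = cross_overlap_volume(placed["stapes_volume"], placed["incus_volume"],
                                h=_OVERLAP_GRID / 2.0)
    params["stapes_volume"] -= lens
    params["incudostapedial_angle_DGI"] = float(joint_angle_deg)

    all_prims = [p for _, prims in labeled_prims for p in prims]
    _check_spacing(all_prims, spacing)
    vol = rasterize_solids(labeled_prims, spacing)
    truth = PhantomGroundTruth(landmarks, params)
    truth.check_self_consistent()
    return vol, truth


def random_chain_inputs(rng: np.random.Generator):
    """Draw one randomized chain phantom configuration around the population
    means, with the published between-ear standard deviations (clipped to
    +-1.5 SD to stay constructible) and a uniformly random rigid pose."""

    def draw(mean, sd):
        return float(np.clip(rng.normal(mean, sd), mean - 1.5 * sd, mean + 1.5 * sd))

    for _ in range(50):
        try:
            m = MalleusPhantomSpec(
                total_height=draw(7.91, 0.36),
                manubrium_length=draw(4.36, 0.28),
                head_neck_length=draw(4.89, 0.31),
            )
            i = IncusPhantomSpec(
                total_height=draw(6.56, 0.38),
                total_width=draw(4.97, 0.33),
                process_distance=draw(5.55, 0.39),
            )
            s = StapesPhantomSpec(
                total_height=draw(3.25, 0.22),
                footplate_length=draw(2.63, 0.15),
            )
            angle = draw(96.83, 6.03)
            _malleus_canonical(m), _incus_canonical(i), _stapes_canonical(s)
            pose = RigidPose.random(rng)
            return m, i, s, angle, pose
        except (DegenerateGeometryError, ValueError):
            continue
    raise RuntimeError("could not draw a constructible phantom configuration")


# ---------------------------------------------------------------------------
# perturbation harness
# ---------------------------------------------------------------------------

def boundary_voxels(data: np.ndarray) -> np.ndarray:
    """Voxels whose 6-neighborhood mixes foreground and background."""
    fg = data > 0
    mixed = np.zeros_like(fg)
    for axis in range(3):
        for shift in (1, -1):
            nb = np.roll(fg, shift, axis=axis)
            # roll wraps; edge slices are cleared so the border never mixes
            sl = [slice(None)] * 3
            sl[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
            nb[tuple(sl)] = fg[tuple(sl)]
            mixed |= fg != nb
    return mixed


def perturb_volume(
    vol: LabelVolume, boundary_flip_prob: float, seed: int
) -> LabelVolume:
    """Flip boundary voxels with the given probability (seeded, reproducible).

    Foreground boundary voxels become background; background boundary voxels
    take the most frequent neighboring label (smallest label on ties).
    Interior voxels are never touched.
    """
    if not (0.0 <= boundary_flip_prob <= 0.5):
        raise ValueError("boundary_flip_prob must be in [0, 0.5]")
    data = vol.data.copy()
    if boundary_flip_prob == 0.0:
        return LabelVolume(data, vol.spacing, vol.origin, vol.axis_orientation)
    rng = np.random.default_rng(seed)
    boundary = boundary_voxels(data)
    flip = boundary & (rng.random(data.shape) < boundary_flip_prob)
    fg_flip = flip & (data > 0)
    bg_flip = flip & (data == 0)
    # majority label among 6-neighbors for promoted background voxels
    labels = [l for l in np.unique(data) if l > 0]
    counts = np.zeros((len(labels),) + data.shape, dtype=np.int8)
    for li, lab in enumerate(labels):
        m = data == lab
        for axis in range(3):
            for shift in (1, -1):
                nb = np.roll(m, shift, axis=axis)
                sl = [slice(None)] * 3
                sl[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
                nb[tuple(sl)] = False
                counts[li] += nb
    winner = np.asarray(labels, dtype=data.dtype)[np.argmax(counts, axis=0)]
    data[fg_flip] = 0
    data[bg_flip] = winner[bg_flip]
    return LabelVolume(data, vol.spacing, vol.origin, vol.axis_orientation)
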