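"""Differential-geometry features and anatomical landmark detection.

Stage 2 of the pipeline: per-vertex Gaussian/mean curvature maps, the
oriented (minimum) bounding box, exact farthest point pairs, protrusion-tip
detection, the footplate major-axis estimator, and the per-ossicle landmark
locators that map geometric signatures to the named points A–J.

Conventions
-----------
* Gaussian curvature: angle deficit over the Meyer mixed Voronoi area
  (1/mm^2). Summed over a closed genus-0 mesh the raw deficits obey
  Gauss–Bonnet (total 4*pi).
* Mean curvature: cotangent-Laplacian mean-curvature normal, signed by the
  outward vertex normal, so convex regions have H > 0 (sphere of radius r:
  H = 1/r, K = 1/r^2).
* All ties are broken lexicographically on (x, y, z) for bit-reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError

from .errors import DegenerateGeometryError, FootplateNotFoundError, LandmarkNotFoundError

# default detection thresholds; exposed via RunConfig and chosen on phantoms
MIN_GAUSS_DEFAULT = 4.0        # 1/mm^2 — tips must curve tighter than r ~ 0.5 mm
NMS_RADIUS_DEFAULT = 0.4       # mm — merge tip candidates closer than this
PLANAR_H_THRESHOLD = 0.5       # 1/mm — |H| below this counts as flat (footplate)
PLANE_RMS_THRESHOLD = 0.08     # mm — max plane-fit RMS for a footplate cluster
FOOTPLATE_BAND = 0.5           # mm — plane-distance band defining the footplate region
AMBIGUITY_RATIO = 1.05         # end-thickness / axis-eigenvalue ambiguity gate


@dataclass
class CurvatureMap:
    """Per-vertex discrete curvatures of a triangle mesh."""

    gaussian: np.ndarray  # 1/mm^2
    mean: np.ndarray      # 1/mm, signed (convex > 0)
    vertex_area: np.ndarray  # mixed Voronoi area, mm^2

    @property
    def total_gaussian(self) -> float:
        """Integrated Gaussian curvature = sum of angle deficits (Gauss-Bonnet)."""
        return float(np.sum(self.gaussian * self.vertex_area))


@dataclass
class OrientedBoundingBox:
    center: np.ndarray
    axes: np.ndarray       # rows, orthonormal, sorted by extent descending
    extents: np.ndarray    # mm, descending

    @property
    def volume(self) -> float:
        return float(np.prod(self.extents))

    def contains(self, pts: np.ndarray, inflate: float = 1e-6) -> np.ndarray:
        local = np.abs((pts - self.center) @ self.axes.T)
        return np.all(local <= self.extents / 2.0 + inflate, axis=-1)


@dataclass
class PrincipalAxis:
    direction: np.ndarray
    length: float
    centroid: np.ndarray


@dataclass
class FeaturePointSet:
    """Named landmarks in mm with the detection rule that produced each."""

    points: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add(self, name: str, point: np.ndarray, rule: str) -> None:
        self.points[name] = np.asarray(point, dtype=float)
        self.provenance[name] = rule

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]


@dataclass
class ProtrusionTip:
    point: np.ndarray
    vertex_index: int
    peak_gaussian: float
    direction: np.ndarray  # outward mean normal of the tip cluster


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

def compute_vertex_curvatures(mesh: trimesh.Trimesh) -> CurvatureMap:
    """Discrete Gaussian (angle deficit / mixed area) and mean (cotangent
    Laplacian) curvature at every vertex of a watertight mesh."""
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces)
    tri = verts[faces]  # (F, 3, 3)
    # edge vectors opposite each corner: e_c = x_b - x_a for corner order
    e = np.stack([tri[:, 2] - tri[:, 1], tri[:, 0] - tri[:, 2], tri[:, 1] - tri[:, 0]],
                 axis=1)  # (F, 3corner, 3)
    lsq = np.einsum("fci,fci->fc", e, e)
    if np.any(lsq <= 0):
        bad = np.unique(np.where(lsq <= 0)[0])
        raise DegenerateGeometryError(f"zero-length edges in faces {bad[:20].tolist()}")
    double_area = np.linalg.norm(np.cross(e[:, 1], e[:, 2]), axis=1)
    if np.any(double_area <= 1e-14):
        bad = np.where(double_area <= 1e-14)[0]
        raise DegenerateGeometryError(
            f"degenerate (zero-area) faces: {bad[:20].tolist()}; clean the mesh first"
        )
    # corner angles via the cross/dot of the two edges leaving each corner
    angles = np.empty_like(lsq)
    for c in range(3):
        u, v = -e[:, (c + 1) % 3], e[:, (c + 2) % 3]
        cosang = np.einsum("fi,fi->f", u, v)
        sinang = np.linalg.norm(np.cross(u, v), axis=1)
        angles[:, c] = np.arctan2(sinang, cosang)
    cot = np.cos(angles) / np.maximum(np.sin(angles), 1e-12)

    n_v = len(verts)
    # Meyer mixed Voronoi area
    area_mixed = np.zeros(n_v)
    face_area = double_area / 2.0
    obtuse_corner = angles > np.pi / 2.0
    any_obtuse = obtuse_corner.any(axis=1)
    # non-obtuse triangles: Voronoi corner areas (|e_b|^2 cot_b + |e_c|^2 cot_c)/8
    vor = np.zeros_like(lsq)
    for c in range(3):
        b, cc = (c + 1) % 3, (c + 2) % 3
        vor[:, c] = (lsq[:, b] * cot[:, b] + lsq[:, cc] * cot[:, cc]) / 8.0
    safe = ~any_obtuse
    np.add.at(area_mixed, faces[safe].ravel(), vor[safe].ravel())
    # obtuse triangles: half the area at the obtuse corner, quarter elsewhere
    ob = any_obtuse
    share = np.where(obtuse_corner[ob], 0.5, 0.25) * face_area[ob, None]
    np.add.at(area_mixed, faces[ob].ravel(), share.ravel())

    deficit = np.full(n_v, 2.0 * np.pi)
    np.add.at(deficit, faces.ravel(), -angles.ravel())
    gaussian = deficit / np.maximum(area_mixed, 1e-12)

    # cotangent Laplacian mean-curvature normal:
    #   Hvec_i = sum_j (cot a_ij + cot b_ij) (x_i - x_j) / (2 A_i) = 2 H n_i
    hvec = np.zeros((n_v, 3))
    for c in range(3):
        a_idx, b_idx = faces[:, (c + 1) % 3], faces[:, (c + 2) % 3]
        w = cot[:, c][:, None]
        diff = verts[a_idx] - verts[b_idx]
        np.add.at(hvec, a_idx, w * diff)
        np.add.at(hvec, b_idx, -w * diff)
    hvec /= 2.0 * np.maximum(area_mixed, 1e-12)[:, None]
    normals = np.asarray(mesh.vertex_normals)
    mean = 0.5 * np.einsum("ij,ij->i", hvec, normals)
    return CurvatureMap(gaussian=gaussian, mean=mean, vertex_area=area_mixed)


def smooth_vertex_scalars(
    mesh: trimesh.Trimesh, values: np.ndarray, iterations: int = 3
) -> np.ndarray:
    """Neighbor-average a per-vertex scalar field a few times.

    Voxelization ripple produces alternating-sign curvature noise at the
    one-edge scale; a couple of umbrella-averaging passes cancels it while
    coherent features (protrusion caps, flat plates) survive. Used for
    detection thresholds only — never to alter geometry.
    """
    edges = mesh.edges_unique
    n_v = len(mesh.vertices)
    rows = np.concatenate([edges[:, 0], edges[:, 1], np.arange(n_v)])
    cols = np.concatenate([edges[:, 1], edges[:, 0], np.arange(n_v)])
    w = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n_v, n_v))
    deg = np.asarray(w.sum(axis=1)).ravel()
    w = w.multiply(1.0 / deg[:, None]).tocsr()
    out = np.asarray(values, dtype=float)
    for _ in range(iterations):
        out = w @ out
    return out


# ---------------------------------------------------------------------------
# bounding boxes
# ---------------------------------------------------------------------------

def _canonical_axes(axes: np.ndarray) -> np.ndarray:
    """Deterministic sign/handedness convention for box axes."""
    axes = axes.copy()
    for i in range(3):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return axes


def compute_obb(mesh: trimesh.Trimesh | np.ndarray) -> OrientedBoundingBox:
    """Near-minimal oriented bounding box (convex-hull rotating search).

    Requires at least 4 non-coplanar vertices; raises
    ``DegenerateGeometryError`` otherwise.
    """
    pts = np.asarray(mesh.vertices if hasattr(mesh, "vertices") else mesh, dtype=float)
    if len(pts) < 4:
        raise DegenerateGeometryError("need >= 4 points for an oriented bounding box")
    centered = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[-1] < 1e-9 * max(svals[0], 1.0):
        raise DegenerateGeometryError("points are coplanar/collinear; box is degenerate")
    to_origin, extents = trimesh.bounds.oriented_bounds(pts)
    rot = to_origin[:3, :3]
    center = -rot.T @ to_origin[:3, 3]
    order = np.argsort(extents)[::-1]
    axes = _canonical_axes(rot[order])
    return OrientedBoundingBox(center=center, axes=axes,
                               extents=np.asarray(extents, dtype=float)[order])


def pca_bounding_box(points: np.ndarray) -> OrientedBoundingBox:
    """Plain PCA-aligned box (no rotation refinement); reference construction."""
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    local = (pts - centroid) @ vt.T
    lo, hi = local.min(axis=0), local.max(axis=0)
    extents = hi - lo
    center = centroid + vt.T @ ((lo + hi) / 2.0)
    order = np.argsort(extents)[::-1]
    return OrientedBoundingBox(center=center, axes=_canonical_axes(vt[order]),
                               extents=extents[order])


# ---------------------------------------------------------------------------
# farthest pairs
# ---------------------------------------------------------------------------

def _hull_candidates(pts: np.ndarray) -> np.ndarray:
    if len(pts) < 16:
        return pts
    try:
        return pts[ConvexHull(pts).vertices]
    except QhullError:
        return pts


def _lex_first(pairs: np.ndarray) -> int:
    """Index of the lexicographically smallest row."""
    order = np.lexsort(pairs.T[::-1])
    return int(order[0])


def farthest_point_pair(
    region_a: np.ndarray, region_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact maximizer of pairwise distance between two point sets.

    Convex-hull pruning keeps this exact (the diameter of a finite set is
    attained at hull vertices) while fast; ties are broken lexicographically
    on the concatenated coordinates.
    """
    a = np.asarray(region_a, dtype=float).reshape(-1, 3)
    b = np.asarray(region_b, dtype=float).reshape(-1, 3)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("farthest_point_pair requires non-empty regions")
    ca, cb = _hull_candidates(a), _hull_candidates(b)
    d2 = np.sum((ca[:, None, :] - cb[None, :, :]) ** 2, axis=-1)
    dmax = d2.max()
    ii, jj = np.where(d2 >= dmax - 1e-12)
    pairs = np.hstack([ca[ii], cb[jj]])
    k = _lex_first(pairs)
    return ca[ii[k]].copy(), cb[jj[k]].copy(), float(np.sqrt(d2[ii[k], jj[k]]))


# ---------------------------------------------------------------------------
# protrusion tips
# ---------------------------------------------------------------------------

def detect_protrusion_tips(
    mesh: trimesh.Trimesh,
    curv: CurvatureMap,
    min_gauss: float = MIN_GAUSS_DEFAULT,
    nms_radius: float = NMS_RADIUS_DEFAULT,
    min_area: float = 0.05,
) -> list[ProtrusionTip]:
    """Convex high-curvature caps, one tip per cap.

    Candidate vertices (K >= min_gauss, H > 0, i.e. convex) are grouped into
    connected clusters; within each cluster the tip is the support maximizer
    along the cluster's mean outward normal, computed over the high-curvature
    core of the cluster. On a capsule this returns exactly the two cap
    apices. Clusters carrying less than ``min_area`` mm^2 of surface are
    discarded: genuine anatomical caps span many vertices, whereas
    segmentation-noise spikes curve just as tightly but cover almost no
    area. Tips are sorted by peak Gaussian curvature and non-maximum
    suppressed within ``nms_radius``.
    """
    if nms_radius <= 0:
        raise ValueError("nms_radius must be positive")
    gauss = smooth_vertex_scalars(mesh, curv.gaussian)
    mean = smooth_vertex_scalars(mesh, curv.mean)
    cand = (gauss >= min_gauss) & (mean > 0)
    idx = np.where(cand)[0]
    if len(idx) == 0:
        return []
    remap = -np.ones(len(mesh.vertices), dtype=int)
    remap[idx] = np.arange(len(idx))
    edges = mesh.edges_unique
    keep = cand[edges[:, 0]] & cand[edges[:, 1]]
    e = remap[edges[keep]]
    graph = csr_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(len(idx), len(idx))
    )
    n_comp, labels = connected_components(graph, directed=False)
    verts = np.asarray(mesh.vertices)
    normals = np.asarray(mesh.vertex_normals)
    tips: list[ProtrusionTip] = []
    for comp in range(n_comp):
        members = idx[labels == comp]
        if curv.vertex_area[members].sum() < min_area:
            continue
        k_vals = gauss[members]
        k_ref = float(np.quantile(k_vals, 0.9))
        core = members[k_vals >= 0.5 * k_ref]
        n_bar = normals[core].mean(axis=0)
        nrm = np.linalg.norm(n_bar)
        if nrm < 1e-9:  # closed shell of curvature (e.g. a whole small sphere)
            continue
        n_bar /= nrm
        support = verts[core] @ n_bar
        smax = support.max()
        best = core[support >= smax - 1e-12]
        vi = best[_lex_first(verts[best])]
        tips.append(ProtrusionTip(point=verts[vi].copy(), vertex_index=int(vi),
                                  peak_gaussian=k_ref, direction=n_bar))
    tips.sort(key=lambda t: -t.peak_gaussian)
    kept: list[ProtrusionTip] = []
    for t in tips:
        if all(np.linalg.norm(t.point - k.point) >= nms_radius for k in kept):
            kept.append(t)
    return kept


# ---------------------------------------------------------------------------
# footplate major axis
# ---------------------------------------------------------------------------

def footplate_major_axis(
    region_points: np.ndarray,
) -> tuple[PrincipalAxis, np.ndarray, np.ndarray]:
    """PCA major axis of a near-planar vertex region and its extreme points.

    Total-least-squares plane fit, 2D projection, PCA; H and J are the
    extreme projected vertices along the first component (their 3D distance
    is the footplate length HJ). Interior holes (perforations) cannot affect
    the result because the extremes lie on the rim. A near-isotropic
    projection (eigenvalue ratio < 1.05) raises an ambiguous-axis warning
    but the axis is still returned deterministically.
    """
    pts = np.asarray(region_points, dtype=float).reshape(-1, 3)
    if len(pts) < 10:
        raise ValueError("footplate region needs at least 10 vertices")
    centroid = pts.mean(axis=0)
    _, svals, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if svals[1] < 1e-12:
        raise DegenerateGeometryError("footplate region is collinear")
    if (svals[0] / svals[1]) ** 2 < AMBIGUITY_RATIO:
        warnings.warn(
            "footplate projection is nearly isotropic; major axis is ambiguous",
            stacklevel=2,
        )
    major = vt[0]
    j_hint = int(np.argmax(np.abs(major)))
    if major[j_hint] < 0:
        major = -major
    proj = (pts - centroid) @ major
    for target, sel in (("lo", proj <= proj.min() + 1e-12),
                        ("hi", proj >= proj.max() - 1e-12)):
        cand = pts[sel]
        pick = cand[_lex_first(cand)]
        if target == "lo":
            h_pt = pick
        else:
            j_pt = pick
    axis = PrincipalAxis(direction=major, length=float(proj.max() - proj.min()),
                         centroid=centroid)
    return axis, h_pt, j_pt


# ---------------------------------------------------------------------------
# landmark locators
# ---------------------------------------------------------------------------

FLAT_MAX_TOL = 0.01  # mm of score slack treated as "tied" at a flat maximum


def _flat_max_point(mesh: trimesh.Trimesh, points: np.ndarray, score: np.ndarray,
                    tol: float = FLAT_MAX_TOL) -> np.ndarray:
    """Stable maximizer of a flat (quadratically degenerate) score.

    Distance-type scores are nearly constant over a cap around the true
    maximizer, so the raw argmax wanders with mesh noise. The centroid of
    the near-optimal set, projected back onto the surface, recovers the cap
    center deterministically (and stays on the mesh).
    """
    sel = score >= score.max() - tol
    centroid = points[sel].mean(axis=0)
    return _project_to_surface(mesh, centroid)


def _project_to_surface(mesh: trimesh.Trimesh, point: np.ndarray,
                        n_near: int = 30) -> np.ndarray:
    """Exact closest point on the mesh, searched over the faces incident to
    the nearest vertices (sufficient for points already near the surface)."""
    verts = np.asarray(mesh.vertices)
    d = np.linalg.norm(verts - point, axis=1)
    near = np.argpartition(d, min(n_near, len(d) - 1))[:n_near]
    fmask = np.isin(mesh.faces, near).any(axis=1)
    tris = mesh.triangles[fmask]
    candidates = trimesh.triangles.closest_point(tris, np.tile(point, (len(tris), 1)))
    dist = np.linalg.norm(candidates - point, axis=1)
    return candidates[int(np.argmin(dist))].copy()


def _refined_farthest_pair(mesh: trimesh.Trimesh,
                           verts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Farthest pair with flat-maximum stabilization of both endpoints."""
    p, q, _ = farthest_point_pair(verts, verts)
    # refine each end against the *raw* partner so the result does not
    # depend on the (tie-broken) ordering of the pair
    p_ref = _flat_max_point(mesh, verts, np.linalg.norm(verts - q, axis=1))
    q_ref = _flat_max_point(mesh, verts, np.linalg.norm(verts - p, axis=1))
    return p_ref, q_ref

def _local_end_area(verts: np.ndarray, areas: np.ndarray, end: np.ndarray,
                    radius: float = 0.9) -> float:
    """Surface area within a Euclidean ball around an extreme point.

    A thick end (head/body) carries much more nearby surface than a thin
    process tip; unlike a slice perpendicular to the global principal axis
    this is insensitive to how bent the ossicle is.
    """
    sel = np.linalg.norm(verts - end, axis=1) <= radius
    return float(areas[sel].sum())


def _assign_ends(
    verts: np.ndarray, p: np.ndarray, q: np.ndarray,
    vertex_areas: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Order an extreme pair as (thick end, thin end) by local cross-section."""
    thick_p = _local_end_area(verts, vertex_areas, p)
    thick_q = _local_end_area(verts, vertex_areas, q)
    ratio = max(thick_p, thick_q) / max(min(thick_p, thick_q), 1e-9)
    ambiguous = ratio < AMBIGUITY_RATIO
    if ambiguous:
        # deterministic fallback: lexicographically smaller point is the "thick" end
        pair = np.vstack([p, q])
        first = _lex_first(pair)
        thick, thin = (p, q) if first == 0 else (q, p)
    elif thick_p >= thick_q:
        thick, thin = p, q
    else:
        thick, thin = q, p
    return thick, thin, ratio, ambiguous


def locate_malleus_landmarks(
    mesh: trimesh.Trimesh,
    curv: CurvatureMap | None = None,
    obb: OrientedBoundingBox | None = None,
    min_gauss: float = MIN_GAUSS_DEFAULT,
    nms_radius: float = NMS_RADIUS_DEFAULT,
) -> FeaturePointSet:
    """A = head apex, C = manubrium tip (farthest pair, head = thicker end);
    B = highest-curvature protrusion tip in the central axis band."""
    curv = curv or compute_vertex_curvatures(mesh)
    obb = obb or compute_obb(mesh)
    verts = np.asarray(mesh.vertices)
    p, q = _refined_farthest_pair(mesh, verts)
    fps = FeaturePointSet()
    a_pt, c_pt, ratio, ambiguous = _assign_ends(verts, p, q, curv.vertex_area)
    if ambiguous:
        fps.warnings.append(
            f"head/tip cross-sections nearly equal (ratio {ratio:.3f}); "
            "A/C assigned lexicographically"
        )
    fps.add("A", a_pt, "farthest-pair end with larger cross-section (head)")
    fps.add("C", c_pt, "farthest-pair end with smaller cross-section (manubrium tip)")
    t = verts @ obb.axes[0]
    lo, hi = t.min(), t.max()
    band_lo, band_hi = lo + 0.25 * (hi - lo), lo + 0.75 * (hi - lo)
    tips = detect_protrusion_tips(mesh, curv, min_gauss=min_gauss, nms_radius=nms_radius)
    in_band = [tp for tp in tips if band_lo <= tp.point @ obb.axes[0] <= band_hi]
    if not in_band:
        raise LandmarkNotFoundError(
            "B", "no protrusion tip in the central axis band (lateral process missing?)"
        )
    # the lateral process is the most *lateral* tip: of the convex caps in the
    # central band, take the one farthest from the head-tip line (much more
    # stable under boundary noise than ranking by peak curvature)
    ac_dir = (c_pt - a_pt) / np.linalg.norm(c_pt - a_pt)

    def lateral_distance(pt: np.ndarray) -> float:
        rel = pt - a_pt
        return float(np.linalg.norm(rel - (rel @ ac_dir) * ac_dir))

    b_tip = max(in_band, key=lambda tp: lateral_distance(tp.point))
    fps.add("B", b_tip.point,
            "most lateral protrusion tip in central 50% axis band")
    return fps


def locate_incus_landmarks(
    mesh: trimesh.Trimesh,
    curv: CurvatureMap | None = None,
    obb: OrientedBoundingBox | None = None,
    stapes_points: np.ndarray | None = None,
    min_gauss: float = MIN_GAUSS_DEFAULT,
    nms_radius: float = NMS_RADIUS_DEFAULT,
) -> FeaturePointSet:
    """D = body top, G = long-process tip (farthest pair); F = short-process
    tip (protrusion farthest from line DG); E = body point farthest from F."""
    curv = curv or compute_vertex_curvatures(mesh)
    obb = obb or compute_obb(mesh)
    verts = np.asarray(mesh.vertices)
    p, q = _refined_farthest_pair(mesh, verts)
    fps = FeaturePointSet()
    if stapes_points is not None and len(stapes_points):
        sp = np.asarray(stapes_points, dtype=float).reshape(-1, 3)
        dp = np.min(np.linalg.norm(sp - p, axis=1))
        dq = np.min(np.linalg.norm(sp - q, axis=1))
        g_pt, d_pt = (p, q) if dp <= dq else (q, p)
        rule_g = "farthest-pair end nearer the stapes head"
    else:
        d_pt, g_pt, ratio, ambiguous = _assign_ends(verts, p, q, curv.vertex_area)
        rule_g = "farthest-pair end with smaller cross-section (long process)"
        if ambiguous:
            fps.warnings.append(
                f"incus end cross-sections nearly equal (ratio {ratio:.3f}); "
                "D/G assigned lexicographically"
            )
    fps.add("D", d_pt, "farthest-pair end at the incus body top")
    fps.add("G", g_pt, rule_g)
    tips = detect_protrusion_tips(mesh, curv, min_gauss=min_gauss, nms_radius=nms_radius)
    if len(tips) < 2:
        raise LandmarkNotFoundError(
            "F", f"need >= 2 protrusion tips to separate the processes, found {len(tips)}"
        )
    dg = g_pt - d_pt
    dg_hat = dg / np.linalg.norm(dg)
    def dist_to_line(pt):
        rel = pt - d_pt
        return float(np.linalg.norm(rel - (rel @ dg_hat) * dg_hat))
    f_tip = max(tips, key=lambda tp: dist_to_line(tp.point))
    fps.add("F", f_tip.point, "protrusion tip farthest from line DG (short process)")
    s = (verts - g_pt) @ (-dg_hat)  # axis coordinate from G toward D
    body = verts[s > np.linalg.norm(dg) / 2.0]
    if len(body) == 0:
        raise LandmarkNotFoundError("E", "no vertices in the body half of the incus")
    e_pt = _flat_max_point(mesh, body, np.linalg.norm(body - f_tip.point, axis=1))
    fps.add("E", e_pt, "body vertex maximizing distance to F")
    return fps


def locate_stapes_landmarks(
    mesh: trimesh.Trimesh,
    curv: CurvatureMap | None = None,
    obb: OrientedBoundingBox | None = None,
    incus_g: np.ndarray | None = None,
    planar_h_threshold: float = PLANAR_H_THRESHOLD,
    plane_rms_threshold: float = PLANE_RMS_THRESHOLD,
    footplate_band: float = FOOTPLATE_BAND,
) -> FeaturePointSet:
    """Footplate = largest near-planar cluster; G_s = head apex (snapped to
    the incus long-process tip when provided); I = footplate point farthest
    from the head; H, J = footplate major-axis extremes."""
    curv = curv or compute_vertex_curvatures(mesh)
    verts = np.asarray(mesh.vertices)
    flat = np.abs(smooth_vertex_scalars(mesh, curv.mean)) < planar_h_threshold
    idx = np.where(flat)[0]
    if len(idx) < 10:
        raise FootplateNotFoundError("too few planar vertices for a footplate")
    remap = -np.ones(len(verts), dtype=int)
    remap[idx] = np.arange(len(idx))
    edges = mesh.edges_unique
    keep = flat[edges[:, 0]] & flat[edges[:, 1]]
    e = remap[edges[keep]]
    graph = csr_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])),
                       shape=(len(idx), len(idx)))
    n_comp, labels = connected_components(graph, directed=False)
    sizes = np.bincount(labels)
    plane_pt = plane_n = None
    for comp in np.argsort(sizes)[::-1]:
        members = idx[labels == comp]
        if len(members) < 10:
            break
        pts = verts[members]
        centroid = pts.mean(axis=0)
        _, svals, vt = np.linalg.svd(pts - centroid, full_matrices=False)
        rms = svals[2] / np.sqrt(len(pts))
        if rms < plane_rms_threshold:
            plane_pt, plane_n = centroid, vt[2]
            break
    if plane_pt is None:
        raise FootplateNotFoundError()
    signed = (verts - plane_pt) @ plane_n
    # orient the normal toward the head (the side with the farthest vertex)
    if abs(signed.min()) > abs(signed.max()):
        plane_n, signed = -plane_n, -signed
    fps = FeaturePointSet()
    if incus_g is not None:
        gi = int(np.argmin(np.linalg.norm(verts - np.asarray(incus_g), axis=1)))
        g_pt = verts[gi]
        rule_g = "stapes vertex nearest the incus long-process tip"
    else:
        cand = verts[signed >= signed.max() - 1e-12]
        g_pt = cand[_lex_first(cand)]
        rule_g = "vertex farthest from the footplate plane (head apex)"
    fps.add("G_s", g_pt, rule_g)
    region = verts[(signed >= -footplate_band) & (signed <= footplate_band)]
    axis, h_pt, j_pt = footplate_major_axis(region)
    fps.add("H", h_pt, "footplate major-axis extreme (low end)")
    fps.add("J", j_pt, "footplate major-axis extreme (high end)")
    i_pt = _flat_max_point(mesh, region, np.linalg.norm(region - g_pt, axis=1))
    fps.add("I", i_pt, "footplate vertex farthest from the head")
    return fps
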