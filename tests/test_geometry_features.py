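"""Curvature maps, bounding boxes, farthest pairs, tips, landmark locators."""

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from ossimetry import geometry_features as gf
from ossimetry.errors import (
    DegenerateGeometryError,
    FootplateNotFoundError,
    LandmarkNotFoundError,
)

# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

def test_icosphere_gaussian_and_mean_curvature():
    sph = trimesh.creation.icosphere(subdivisions=4, radius=2.0)
    curv = gf.compute_vertex_curvatures(sph)
    assert curv.gaussian.mean() == pytest.approx(0.25, rel=0.05)
    assert curv.mean.mean() == pytest.approx(0.5, rel=0.05)  # convex => positive


def test_flat_grid_interior_gaussian_curvature_zero():
    n = 8
    xx, yy = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    verts = np.stack([xx.ravel(), yy.ravel(), np.zeros(n * n)], axis=1)
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a, b, c, d = i * n + j, i * n + j + 1, (i + 1) * n + j, (i + 1) * n + j + 1
            faces += [[a, b, d], [a, d, c]]
    patch = trimesh.Trimesh(verts, np.asarray(faces), process=False)
    curv = gf.compute_vertex_curvatures(patch)
    interior = [i * n + j for i in range(1, n - 1) for j in range(1, n - 1)]
    assert np.max(np.abs(curv.gaussian[interior])) < 1e-8


@pytest.mark.parametrize("mesh_name", ["icosphere", "capsule_mesh", "malleus_mesh"])
def test_gauss_bonnet_total_curvature(mesh_name, request):
    """Total angle deficit of every closed genus-0 mesh is 4*pi (to 1e-6)."""
    mesh = request.getfixturevalue(mesh_name)
    assert mesh.euler_number == 2
    curv = gf.compute_vertex_curvatures(mesh)
    assert curv.total_gaussian == pytest.approx(4 * np.pi, abs=1e-6)


def test_degenerate_faces_rejected():
    verts = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
    mesh = trimesh.Trimesh(verts, [[0, 1, 3], [1, 2, 3]], process=False)
    with pytest.raises(DegenerateGeometryError):
        gf.compute_vertex_curvatures(mesh)


# ---------------------------------------------------------------------------
# oriented bounding box
# ---------------------------------------------------------------------------

def _box_cloud(extents, rot=None, n=200, seed=0):
    rng = np.random.default_rng(seed)
    pts = (rng.random((n, 3)) - 0.5) * np.asarray(extents)
    corners = (np.array(np.meshgrid([-.5, .5], [-.5, .5], [-.5, .5]))
               .T.reshape(-1, 3) * np.asarray(extents))
    pts = np.vstack([pts, corners])
    if rot is not None:
        pts = pts @ rot.T
    return pts


def test_obb_axis_aligned_box():
    pts = _box_cloud((2.0, 1.0, 0.5))
    obb = gf.compute_obb(pts)
    np.testing.assert_allclose(obb.extents, [2.0, 1.0, 0.5], atol=1e-9)
    assert obb.volume == pytest.approx(1.0, abs=1e-9)
    assert np.all(obb.contains(pts))


def test_obb_rotation_invariant_extents():
    rot = Rotation.from_euler("z", 30, degrees=True).as_matrix()
    obb = gf.compute_obb(_box_cloud((2.0, 1.0, 0.5), rot=rot))
    np.testing.assert_allclose(obb.extents, [2.0, 1.0, 0.5], atol=1e-6)
    assert obb.volume == pytest.approx(1.0, abs=1e-6)


def test_obb_beats_rotation_grid_oracle_on_boxes():
    """OBB volume within 1% of a 0.5-degree z-rotation grid search."""
    rot = Rotation.from_euler("z", 17, degrees=True).as_matrix()
    pts = _box_cloud((2.0, 1.0, 0.5), rot=rot)
    best = np.inf
    for deg in np.arange(0.0, 90.0, 0.5):
        r = Rotation.from_euler("z", deg, degrees=True).as_matrix()
        local = pts @ r.T
        best = min(best, float(np.prod(local.max(0) - local.min(0))))
    obb = gf.compute_obb(pts)
    assert obb.volume <= best * 1.01


def test_obb_no_worse_than_pca_box():
    rng = np.random.default_rng(2)
    pts = np.array([[0, 0, 0], [1, 0, 0], [0.5, 1, 0], [0.5, 0.5, 1.2]], dtype=float)
    pts = np.vstack([pts, pts.mean(axis=0) + rng.normal(0, 0.05, (30, 3))])
    obb = gf.compute_obb(pts)
    pca = gf.pca_bounding_box(pts)
    assert obb.volume <= pca.volume + 1e-9


def test_obb_rejects_coplanar_points():
    pts = np.random.default_rng(0).random((50, 3))
    pts[:, 2] = 0.0
    with pytest.raises(DegenerateGeometryError):
        gf.compute_obb(pts)


# ---------------------------------------------------------------------------
# farthest point pair
# ---------------------------------------------------------------------------

def test_farthest_pair_unit_cube_diagonal():
    corners = np.array(np.meshgrid([0, 1], [0, 1], [0, 1])).T.reshape(-1, 3).astype(float)
    _, _, d = gf.farthest_point_pair(corners, corners)
    assert d == pytest.approx(np.sqrt(3.0), abs=1e-12)


def test_farthest_pair_sphere_diameter(icosphere):
    _, _, d = gf.farthest_point_pair(icosphere.vertices, icosphere.vertices)
    assert d == pytest.approx(2.0, rel=0.01)


@pytest.mark.parametrize("n_points", [50, 500, 2000])
def test_farthest_pair_matches_quadratic_brute_force(n_points):
    rng = np.random.default_rng(n_points)
    pts = rng.normal(0, 1, (n_points, 3)).cumsum(axis=0) / 5.0  # correlated cloud
    p, q, d = gf.farthest_point_pair(pts, pts)
    d2 = np.sum((pts[:, None] - pts[None]) ** 2, axis=-1)
    assert d == pytest.approx(np.sqrt(d2.max()), abs=1e-12)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    assert {tuple(p), tuple(q)} == {tuple(pts[i]), tuple(pts[j])}


def test_farthest_pair_empty_region_rejected():
    with pytest.raises(ValueError):
        gf.farthest_point_pair(np.empty((0, 3)), np.ones((3, 3)))


# ---------------------------------------------------------------------------
# protrusion tips
# ---------------------------------------------------------------------------

def test_capsule_has_exactly_two_tips_at_apices(capsule_mesh):
    curv = gf.compute_vertex_curvatures(capsule_mesh)
    tips = gf.detect_protrusion_tips(capsule_mesh, curv, min_gauss=2.0, nms_radius=0.6)
    assert len(tips) == 2
    apices = sorted(round(t.point[2], 6) for t in tips)
    assert apices == pytest.approx([-1.5, 1.5], abs=1e-6)
    for t in tips:
        assert np.hypot(t.point[0], t.point[1]) < 1e-6


def test_sphere_has_no_tips_above_double_curvature(icosphere):
    curv = gf.compute_vertex_curvatures(icosphere)
    tips = gf.detect_protrusion_tips(icosphere, curv, min_gauss=2.0, nms_radius=0.4)
    assert tips == []


def test_incus_tips_near_process_ends(incus_mesh, incus_phantom):
    _, truth = incus_phantom
    curv = gf.compute_vertex_curvatures(incus_mesh)
    tips = gf.detect_protrusion_tips(incus_mesh, curv)
    tip_pts = np.array([t.point for t in tips])
    for name in ("F", "G"):
        dist = np.min(np.linalg.norm(tip_pts - truth.landmarks[name], axis=1))
        assert dist < 0.2, f"no detected tip within 0.2 mm of {name}"


# ---------------------------------------------------------------------------
# footplate major axis
# ---------------------------------------------------------------------------

def _ellipse_rim(a=1.3, b=0.7, n=400, tilt_deg=25.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.stack([a * np.cos(th), b * np.sin(th), np.zeros(n)], axis=1)
    rot = Rotation.from_euler("xy", [tilt_deg, 10.0], degrees=True).as_matrix()
    return pts @ rot.T, rot[:, 0]


def test_ellipse_rim_major_axis_and_hj():
    pts, true_axis = _ellipse_rim()
    axis, h, j = gf.footplate_major_axis(pts)
    cosang = abs(float(axis.direction @ true_axis))
    assert np.degrees(np.arccos(min(cosang, 1.0))) < 2.0
    assert np.linalg.norm(h - j) == pytest.approx(2.6, rel=0.01)


def test_circle_rim_warns_ambiguous():
    pts, _ = _ellipse_rim(a=1.0, b=1.0)
    with pytest.warns(UserWarning, match="ambiguous"):
        gf.footplate_major_axis(pts)


def test_footplate_region_too_small_rejected():
    with pytest.raises(ValueError):
        gf.footplate_major_axis(np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# landmark locators
# ---------------------------------------------------------------------------

def test_malleus_landmarks_recover_ground_truth(malleus_mesh, malleus_phantom):
    _, truth = malleus_phantom
    fps = gf.locate_malleus_landmarks(malleus_mesh)
    for name in ("A", "B", "C"):
        err = np.linalg.norm(fps[name] - truth.landmarks[name])
        assert err < 0.2, f"{name} off by {err:.3f} mm"
    for pair, key in ((("A", "C"), "malleus_total_height_AC"),
                      (("B", "C"), "malleus_manubrium_BC"),
                      (("A", "B"), "malleus_head_neck_AB")):
        d = np.linalg.norm(fps[pair[0]] - fps[pair[1]])
        assert d == pytest.approx(truth.parameters[key], abs=0.2)


def test_malleus_landmarks_rigid_invariance(malleus_mesh):
    fps = gf.locate_malleus_landmarks(malleus_mesh)
    rot = Rotation.from_euler("xyz", [31, -17, 59], degrees=True).as_matrix()
    moved = malleus_mesh.copy()
    moved.vertices = moved.vertices @ rot.T + np.array([2.0, -1.0, 3.0])
    fps2 = gf.locate_malleus_landmarks(moved)
    for pair in (("A", "C"), ("B", "C"), ("A", "B")):
        d1 = np.linalg.norm(fps[pair[0]] - fps[pair[1]])
        d2 = np.linalg.norm(fps2[pair[0]] - fps2[pair[1]])
        assert d2 == pytest.approx(d1, abs=1e-6)


def test_capsule_has_no_middle_band_tip(capsule_mesh):
    """A featureless capsule has no lateral process: landmark B must fail."""
    with pytest.raises(LandmarkNotFoundError) as exc:
        gf.locate_malleus_landmarks(capsule_mesh, min_gauss=2.0)
    assert exc.value.landmark == "B"


def test_incus_landmarks_recover_ground_truth(incus_mesh, incus_phantom):
    _, truth = incus_phantom
    fps = gf.locate_incus_landmarks(incus_mesh)
    for pair, key in ((("D", "G"), "incus_total_height_DG"),
                      (("E", "F"), "incus_total_width_EF"),
                      (("F", "G"), "incus_process_distance_FG")):
        d = np.linalg.norm(fps[pair[0]] - fps[pair[1]])
        assert d == pytest.approx(truth.parameters[key], abs=0.2)


def test_incus_orients_g_toward_stapes(incus_mesh, incus_phantom):
    _, truth = incus_phantom
    # fake stapes point cloud sitting beyond the true G
    stapes_pts = truth.landmarks["G"] + np.array([0.0, 0.0, -0.5]) \
        + np.random.default_rng(0).normal(0, 0.05, (50, 3))
    fps = gf.locate_incus_landmarks(incus_mesh, stapes_points=stapes_pts)
    assert np.linalg.norm(fps["G"] - truth.landmarks["G"]) < 0.2
    assert np.linalg.norm(fps["D"] - truth.landmarks["D"]) < 0.2


def test_incus_needs_two_tips(icosphere):
    with pytest.raises(LandmarkNotFoundError):
        gf.locate_incus_landmarks(icosphere, min_gauss=2.0)


def test_stapes_landmarks_recover_ground_truth(stapes_mesh, stapes_phantom):
    _, truth = stapes_phantom
    fps = gf.locate_stapes_landmarks(stapes_mesh)
    gi = np.linalg.norm(fps["G_s"] - fps["I"])
    hj = np.linalg.norm(fps["H"] - fps["J"])
    assert gi == pytest.approx(truth.parameters["stapes_total_height_GI"], abs=0.2)
    assert hj == pytest.approx(truth.parameters["stapes_footplate_HJ"], abs=0.15)


def test_stapes_without_footplate_rejected(capsule_mesh):
    with pytest.raises(FootplateNotFoundError):
        gf.locate_stapes_landmarks(capsule_mesh)


def test_malleus_landmarks_mirror_invariance(malleus_mesh):
    """Distances are chirality-free: reflecting the mesh across a plane
    changes no measured distance (within numerical tolerance)."""
    fps = gf.locate_malleus_landmarks(malleus_mesh)
    mirrored = malleus_mesh.copy()
    mirrored.vertices = mirrored.vertices * np.array([-1.0, 1.0, 1.0])
    mirrored.invert()  # restore outward orientation after reflection
    fps_m = gf.locate_malleus_landmarks(mirrored)
    for pair in (("A", "C"), ("B", "C"), ("A", "B")):
        d1 = np.linalg.norm(fps[pair[0]] - fps[pair[1]])
        d2 = np.linalg.norm(fps_m[pair[0]] - fps_m[pair[1]])
        assert d2 == pytest.approx(d1, abs=1e-6)
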