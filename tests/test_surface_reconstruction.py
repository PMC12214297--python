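"""Level sets, marching cubes, windowed-sinc smoothing, enclosed volume."""

import numpy as np
import pytest
import trimesh

from ossimetry import surface_reconstruction as sr
from ossimetry.errors import EmptyInputError, TopologyError
from ossimetry.volume_io import LabelVolume


def _ball_mask(radius_mm=1.0, spacing=0.05, pad=4):
    n = int(2 * radius_mm / spacing) + 2 * pad + 1
    idx = np.arange(n) * spacing
    c = idx[n // 2]  # center on a voxel center so the depth test is aligned
    xx, yy, zz = np.meshgrid(idx, idx, idx, indexing="ij")
    mask = (xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2 <= radius_mm**2
    return LabelVolume(mask.astype(np.uint8), spacing=(spacing,) * 3)


# -- mask_to_levelset -------------------------------------------------------

def test_single_voxel_levelset_minimum_near_half_spacing():
    data = np.zeros((7, 7, 7), dtype=np.uint8)
    data[3, 3, 3] = 1
    phi = sr.mask_to_levelset(LabelVolume(data, spacing=(0.1,) * 3))
    assert phi.values.min() == pytest.approx(-0.05, abs=0.02)


def test_ball_levelset_center_depth_matches_radius():
    vol = _ball_mask(radius_mm=1.0, spacing=0.05)
    phi = sr.mask_to_levelset(vol)
    assert phi.values.min() == pytest.approx(-1.0, abs=0.05)


def test_levelset_empty_and_full_masks_rejected():
    empty = LabelVolume(np.zeros((4, 4, 4), dtype=np.uint8), spacing=(0.1,) * 3)
    full = LabelVolume(np.ones((4, 4, 4), dtype=np.uint8), spacing=(0.1,) * 3)
    with pytest.raises(EmptyInputError):
        sr.mask_to_levelset(empty)
    with pytest.raises(EmptyInputError):
        sr.mask_to_levelset(full)


# -- refine_levelset --------------------------------------------------------

def test_refine_zero_iterations_is_identity():
    vol = _ball_mask(radius_mm=0.5, spacing=0.1)
    phi = sr.mask_to_levelset(vol)
    out = sr.refine_levelset(phi, iterations=0)
    np.testing.assert_array_equal(out.values, phi.values)


def test_refine_negative_iterations_rejected():
    vol = _ball_mask(radius_mm=0.5, spacing=0.1)
    with pytest.raises(ValueError):
        sr.refine_levelset(sr.mask_to_levelset(vol), iterations=-1)


def test_planar_interface_is_a_fixed_point():
    # analytic half-space signed distance: zero curvature, flow leaves it alone
    n = 20
    z = (np.arange(n) - n / 2 + 0.5) * 0.1
    values = np.broadcast_to(z, (n, n, n)).copy()
    phi = sr.LevelSetField(values, (0.1,) * 3, (0.0, 0.0, 0.0))
    out = sr.refine_levelset(phi, iterations=10)
    np.testing.assert_allclose(out.values, phi.values, atol=1e-9)


def test_refine_respects_fidelity_band():
    vol = _ball_mask(radius_mm=0.6, spacing=0.1)
    phi = sr.mask_to_levelset(vol)
    band = 0.05
    out = sr.refine_levelset(phi, iterations=50, fidelity_band=band)
    assert np.max(np.abs(out.values - phi.values)) <= band + 1e-12


def _sphere_rms(mesh):
    c = mesh.vertices.mean(axis=0)
    r = np.linalg.norm(mesh.vertices - c, axis=1)
    return float(np.sqrt(np.mean((r - r.mean()) ** 2)))


def test_refine_reduces_boundary_checkerboard_roughness():
    vol = _ball_mask(radius_mm=0.8, spacing=0.05)
    data = vol.data.copy()
    from ossimetry.phantoms import boundary_voxels

    boundary = boundary_voxels(data)
    ii, jj, kk = np.nonzero(boundary)
    checker = (ii + jj + kk) % 2 == 0
    flip = np.zeros_like(boundary)
    flip[ii[checker], jj[checker], kk[checker]] = True
    data[flip & (data > 0)] = 0
    noisy = LabelVolume(data, vol.spacing)
    phi = sr.mask_to_levelset(noisy)
    rough_before = _sphere_rms(sr.marching_cubes(phi))
    refined = sr.refine_levelset(phi, iterations=10, fidelity_band=0.05)
    rough_after = _sphere_rms(sr.marching_cubes(refined))
    assert rough_after < rough_before


# -- marching_cubes ---------------------------------------------------------

def test_ball_mesh_volume_within_two_percent():
    vol = _ball_mask(radius_mm=1.0, spacing=0.05)
    mesh = sr.marching_cubes(sr.mask_to_levelset(vol))
    assert mesh.is_watertight
    assert mesh.volume == pytest.approx(4.0 * np.pi / 3.0, rel=0.02)


def test_single_voxel_mesh_closed_and_sized():
    data = np.zeros((7, 7, 7), dtype=np.uint8)
    data[3, 3, 3] = 1
    vol = LabelVolume(data, spacing=(0.1,) * 3)
    mesh = sr.marching_cubes(sr.mask_to_levelset(vol))
    assert mesh.is_watertight
    assert mesh.euler_number == 2  # genus 0
    # a 1-voxel object is below the method's resolution: the signed-distance
    # zero crossing through the 6 face midpoints is the inscribed octahedron,
    # whose volume is exactly 1/6 of the voxel
    assert mesh.volume == pytest.approx(1e-3 / 6.0, rel=0.05)


def test_iso_outside_range_raises():
    vol = _ball_mask(radius_mm=0.5, spacing=0.1)
    phi = sr.mask_to_levelset(vol)
    phi.values = np.abs(phi.values) + 1.0  # all positive
    with pytest.raises(EmptyInputError):
        sr.marching_cubes(phi)


def test_mesh_coordinates_in_physical_frame():
    vol = _ball_mask(radius_mm=0.5, spacing=0.1)
    vol.origin = (10.0, -5.0, 2.0)
    mesh = sr.marching_cubes(sr.mask_to_levelset(vol))
    center = mesh.vertices.mean(axis=0)
    expected = np.asarray(vol.origin) + (np.asarray(vol.shape) - 1) / 2.0 * 0.1
    np.testing.assert_allclose(center, expected, atol=0.05)


# -- windowed_sinc_smooth ---------------------------------------------------

def test_smooth_zero_iterations_identical(icosphere):
    out = sr.windowed_sinc_smooth(icosphere, iterations=0)
    np.testing.assert_array_equal(out.vertices, icosphere.vertices)


def test_smooth_preserves_connectivity_and_volume(icosphere):
    out = sr.windowed_sinc_smooth(icosphere, iterations=20, passband=0.1)
    np.testing.assert_array_equal(out.faces, icosphere.faces)
    assert abs(out.volume - icosphere.volume) / icosphere.volume < 0.01


def test_smooth_reduces_radial_jitter(icosphere):
    rng = np.random.default_rng(0)
    noisy = icosphere.copy()
    radial = noisy.vertices / np.linalg.norm(noisy.vertices, axis=1, keepdims=True)
    noisy.vertices = noisy.vertices + radial * rng.normal(0, 0.05, len(radial))[:, None]

    def rms(m):
        return np.sqrt(np.mean((np.linalg.norm(m.vertices, axis=1) - 1.0) ** 2))

    out = sr.windowed_sinc_smooth(noisy, iterations=20, passband=0.1)
    assert rms(out) < rms(noisy)


def test_smooth_rejects_open_meshes_and_bad_passband(icosphere):
    open_mesh = icosphere.copy()
    open_mesh.update_faces(np.arange(len(open_mesh.faces)) > 0)
    with pytest.raises(TopologyError):
        sr.windowed_sinc_smooth(open_mesh, iterations=5)
    with pytest.raises(ValueError):
        sr.windowed_sinc_smooth(icosphere, iterations=5, passband=2.5)


# -- mesh_volume ------------------------------------------------------------

def test_unit_cube_volume_exact():
    cube = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    assert sr.mesh_volume(cube) == pytest.approx(1.0, abs=1e-12)


def test_icosphere_volume_within_half_percent(icosphere):
    assert sr.mesh_volume(icosphere) == pytest.approx(4 * np.pi / 3, rel=0.005)


def test_inward_oriented_cube_fixed_or_rejected():
    cube = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    cube.invert()
    assert cube.volume < 0
    assert sr.mesh_volume(cube, fix_orientation=True) == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(TopologyError):
        sr.mesh_volume(cube, fix_orientation=False)


def test_open_mesh_volume_rejected(icosphere):
    open_mesh = icosphere.copy()
    open_mesh.update_faces(np.arange(len(open_mesh.faces)) > 0)
    with pytest.raises(TopologyError):
        sr.mesh_volume(open_mesh)


def test_end_to_end_volume_consistency(chain_phantom, chain_measurement):
    """Mesh volume, voxel-count volume and analytic volume agree within 3%
    for noise-free phantoms at 0.1 mm."""
    vol, truth = chain_phantom
    meas, qc, _ = chain_measurement
    for name, label in (("malleus", 1), ("incus", 2), ("stapes", 3)):
        analytic = truth.parameters[f"{name}_volume"]
        voxel = qc.voxel_volumes[name]
        mesh_vol = meas[f"{name}_volume"]
        assert abs(mesh_vol - voxel) / analytic < 0.03
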