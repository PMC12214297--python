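"""Binary mask -> refined, smoothed, watertight triangle mesh.

Stage 1 of the measurement pipeline:

1. ``mask_to_levelset`` — signed Euclidean distance field (mm, negative
   inside) with a half-voxel offset so the zero crossing sits on the mask
   boundary faces rather than on voxel centers.
2. ``refine_levelset`` — curvature-regularized level-set smoothing with a
   hard fidelity band: the zero crossing may never drift farther than the
   band from the original mask boundary. This is a documented stand-in for
   the subvoxel "Ricci curvature level set" refinement whose exact
   formulation is published elsewhere; it preserves the stated intent
   (subvoxel refinement, bounded deviation) with a testable contract.
3. ``marching_cubes`` — topology-consistent (Lewiner) iso-surfacing into a
   watertight mesh in mm physical coordinates.
4. ``windowed_sinc_smooth`` — Taubin-style low-pass mesh filter: a
   Hamming-windowed Chebyshev approximation of the ideal low-pass in the
   graph-Laplacian spectral domain. Unlike plain Laplacian smoothing it is
   designed not to shrink the surface.
5. ``mesh_volume`` — divergence-theorem enclosed volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage, sparse
from skimage import measure as sk_measure

from .errors import EmptyInputError, TopologyError
from .volume_io import LabelVolume

__all__ = [
    "LevelSetField",
    "mask_to_levelset",
    "refine_levelset",
    "marching_cubes",
    "windowed_sinc_smooth",
    "mesh_volume",
    "largest_connected_component",
    "mask_to_mesh",
]


@dataclass
class LevelSetField:
    """Scalar field sampled at voxel centers; negative inside the object."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("level-set field must be 3D")

    def copy(self) -> "LevelSetField":
        return LevelSetField(self.values.copy(), self.spacing, self.origin)


def largest_connected_component(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Keep the largest 26-connected foreground component.

    Returns the cleaned mask and the number of discarded islands; the caller
    decides whether discarded islands warrant a QC warning.
    """
    labeled, n = ndimage.label(mask > 0, structure=np.ones((3, 3, 3), dtype=bool))
    if n <= 1:
        return (mask > 0), 0
    counts = np.bincount(labeled.ravel())
    counts[0] = 0
    keep = np.argmax(counts)
    return labeled == keep, n - 1


def mask_to_levelset(mask: LabelVolume, pad: int = 2) -> LevelSetField:
    """Signed Euclidean distance (mm) of a binary mask, negative inside.

    The field is padded by ``pad`` background voxels so an iso-surface never
    touches the array border. The half-voxel offset places the zero crossing
    midway between an inside voxel center and its outside neighbor — i.e. on
    the voxel face, which is the unbiased subvoxel boundary estimate for
    center-inclusion rasterization.
    """
    fg = mask.data > 0
    if not fg.any():
        raise EmptyInputError("mask is empty; no surface to extract")
    if fg.all():
        # padding will create an outside, but a full grid means the object is
        # clipped by the field of view, which the contract rejects
        raise EmptyInputError("mask fills the whole grid; no outside region exists")
    fg = np.pad(fg, pad, mode="constant", constant_values=False)
    spacing = mask.spacing
    h_half = min(spacing) / 2.0
    d_in = ndimage.distance_transform_edt(fg, sampling=spacing)
    d_out = ndimage.distance_transform_edt(~fg, sampling=spacing)
    phi = np.where(fg, -(d_in - h_half), d_out - h_half)
    origin = tuple(o - pad * s for o, s in zip(mask.origin, spacing))
    return LevelSetField(phi, spacing, origin)


def _mean_curvature_times_gradnorm(phi: np.ndarray, spacing) -> np.ndarray:
    """kappa * |grad phi| via divergence of the normalized gradient."""
    grads = np.gradient(phi, *spacing)
    norm = np.sqrt(sum(g * g for g in grads)) + 1e-12
    div = np.zeros_like(phi)
    for axis, g in enumerate(grads):
        div += np.gradient(g / norm, spacing[axis], axis=axis)
    return div * norm


def refine_levelset(
    phi: LevelSetField,
    iterations: int = 5,
    smooth_weight: float = 1.0,
    fidelity_band: float | None = None,
) -> LevelSetField:
    """Mean-curvature-flow smoothing of the zero level set with containment.

    After every step the field is clamped to ``phi0 +- fidelity_band`` so the
    refined interface cannot move farther than the band from the original
    mask boundary (default: half the smallest voxel). ``iterations=0`` is the
    identity; a planar interface is a fixed point (zero curvature).
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    spacing = phi.spacing
    if fidelity_band is None:
        fidelity_band = 0.5 * min(spacing)
    out = phi.copy()
    if iterations == 0:
        return out
    phi0 = phi.values
    h = min(spacing)
    dt = 0.15 * h * h  # explicit curvature-flow stability
    for _ in range(int(iterations)):
        out.values += dt * smooth_weight * _mean_curvature_times_gradnorm(out.values, spacing)
        np.clip(out.values, phi0 - fidelity_band, phi0 + fidelity_band, out=out.values)
    return out


def marching_cubes(phi: LevelSetField, iso: float = 0.0) -> trimesh.Trimesh:
    """Extract the iso-surface as a watertight mesh in mm coordinates."""
    vmin, vmax = float(phi.values.min()), float(phi.values.max())
    if not (vmin < iso < vmax):
        raise EmptyInputError(
            f"iso level {iso} outside field range [{vmin:.3g}, {vmax:.3g}]; empty surface"
        )
    verts, faces, _, _ = sk_measure.marching_cubes(
        phi.values, level=iso, spacing=phi.spacing, method="lewiner"
    )
    verts = verts + np.asarray(phi.origin)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.merge_vertices(merge_tex=True, merge_norm=True)
    mesh.update_faces(mesh.nondegenerate_faces(height=1e-12))
    mesh.remove_unreferenced_vertices()
    # skimage orients normals along the field gradient (inward for signed
    # distance with negative inside); enforce positive enclosed volume
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def is_closed_surface(mesh: trimesh.Trimesh) -> bool:
    """True if the surface has no boundary: every edge borders an even
    number (>= 2) of faces.

    Clean phantom meshes are strictly watertight (exactly 2 everywhere);
    noisy masks can produce non-manifold pinch vertices where 4 faces share
    an edge, which still encloses a well-defined volume.
    """
    _, counts = np.unique(mesh.edges_sorted, axis=0, return_counts=True)
    return bool(len(counts) > 0 and np.all(counts % 2 == 0) and np.all(counts >= 2))


def _windowed_sinc_coefficients(iterations: int, passband: float) -> np.ndarray:
    """Hamming-windowed Chebyshev coefficients of the ideal low-pass.

    Graph-Laplacian eigenvalues live in ``k in [0, 2]``; with ``y = 1 - k``
    the ideal filter (1 below the passband cutoff, 0 above) has Chebyshev
    coefficients ``c_0 = theta/pi, c_i = 2 sin(i theta)/(i pi)`` where
    ``theta = arccos(1 - passband)``. The Hamming window tames the Gibbs
    ringing and the coefficients are renormalized so the DC gain is exactly
    one (no shrinkage of the smooth component).
    """
    n = int(iterations)
    theta = np.arccos(1.0 - passband)
    i = np.arange(1, n + 1)
    c = np.empty(n + 1)
    c[0] = theta / np.pi
    c[1:] = 2.0 * np.sin(i * theta) / (i * np.pi)
    window = 0.54 + 0.46 * np.cos(np.pi * np.arange(n + 1) / (n + 1))
    c *= window
    return c / c.sum()  # filter(k=0) = sum(c_i * T_i(1)) = sum(c_i) = 1


def windowed_sinc_smooth(
    mesh: trimesh.Trimesh, iterations: int = 20, passband: float = 0.1
) -> trimesh.Trimesh:
    """Low-pass filter vertex positions; connectivity is untouched.

    ``iterations`` is the Chebyshev polynomial degree (the number of
    Laplacian applications); ``passband`` in (0, 2) is the normalized cutoff
    frequency. Small passbands smooth more aggressively at fixed degree.
    """
    if not is_closed_surface(mesh):
        raise TopologyError("windowed-sinc smoothing requires a closed surface")
    if not (0.0 < passband < 2.0):
        raise ValueError("passband must lie in (0, 2)")
    if iterations == 0:
        return mesh.copy()
    coeffs = _windowed_sinc_coefficients(iterations, passband)
    # row-normalized adjacency W = I - L (uniform "umbrella" weights)
    edges = mesh.edges_unique
    n_v = len(mesh.vertices)
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    w = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_v, n_v)
    )
    deg = np.asarray(w.sum(axis=1)).ravel()
    w = sparse.diags(1.0 / np.maximum(deg, 1)) @ w
    x = np.asarray(mesh.vertices, dtype=float)
    t_prev, t_cur = x, w @ x  # T_0, T_1 of the shifted operator
    acc = coeffs[0] * t_prev + coeffs[1] * t_cur
    for ci in coeffs[2:]:
        t_prev, t_cur = t_cur, 2.0 * (w @ t_cur) - t_prev
        acc += ci * t_cur
    out = mesh.copy()
    out.vertices = acc
    return out


def mesh_volume(mesh: trimesh.Trimesh, fix_orientation: bool = True) -> float:
    """Enclosed volume (mm^3) by the divergence theorem; requires watertight."""
    if not is_closed_surface(mesh):
        raise TopologyError("cannot compute the enclosed volume of an open mesh")
    vol = float(mesh.volume)
    if vol < 0:
        if not fix_orientation:
            raise TopologyError("mesh is inward-oriented and orientation fixing is off")
        vol = -vol
    return vol


def mask_to_mesh(
    mask: LabelVolume,
    refine_iterations: int = 0,
    fidelity_band_voxels: float = 0.5,
    smooth_iterations: int = 20,
    smooth_passband: float = 0.4,
) -> trimesh.Trimesh:
    """Full stage-1 chain: levelset -> refine -> marching cubes -> smooth."""
    phi = mask_to_levelset(mask)
    phi = refine_levelset(
        phi, iterations=refine_iterations,
        fidelity_band=fidelity_band_voxels * min(mask.spacing),
    )
    mesh = marching_cubes(phi)
    return windowed_sinc_smooth(mesh, iterations=smooth_iterations, passband=smooth_passband)
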