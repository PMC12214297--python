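"""Constructive solid primitives for the ossicle phantoms.

Each primitive knows (a) a vectorized point-membership test, (b) its exact
volume, (c) an axis-aligned bounding box, and (d) how to transform rigidly.
Phantom solids are unions of these; the union volume is the sum of the exact
primitive volumes minus an overlap correction integrated on a fine grid that
is restricted to the (small) pairwise bounding-box intersections — outside
those boxes no overlap can exist, so the identity is exact up to quadrature
error in the overlap lenses only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

Vec = np.ndarray


def _as_vec(x) -> Vec:
    return np.asarray(x, dtype=float).reshape(3)


@dataclass(frozen=True)
class Sphere:
    center: Vec
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec(self.center))
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    def contains(self, pts: Vec) -> np.ndarray:
        d = pts - self.center
        return np.einsum("...i,...i->...", d, d) <= self.radius**2

    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3

    def bbox(self) -> tuple[Vec, Vec]:
        r = self.radius
        return self.center - r, self.center + r

    def transformed(self, rot: np.ndarray, trans: Vec) -> "Sphere":
        return Sphere(rot @ self.center + trans, self.radius)


@dataclass(frozen=True)
class Capsule:
    """Cylinder with hemispherical end caps (tube around a segment)."""

    p0: Vec
    p1: Vec
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "p0", _as_vec(self.p0))
        object.__setattr__(self, "p1", _as_vec(self.p1))
        if self.radius <= 0:
            raise ValueError("capsule radius must be positive")
        if np.allclose(self.p0, self.p1):
            raise ValueError("capsule endpoints coincide; use a Sphere")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    def contains(self, pts: Vec) -> np.ndarray:
        axis = self.p1 - self.p0
        ll = float(axis @ axis)
        t = np.clip(np.einsum("...i,i->...", pts - self.p0, axis) / ll, 0.0, 1.0)
        closest = self.p0 + t[..., None] * axis
        d = pts - closest
        return np.einsum("...i,...i->...", d, d) <= self.radius**2

    def volume(self) -> float:
        return np.pi * self.radius**2 * self.length + 4.0 / 3.0 * np.pi * self.radius**3

    def bbox(self) -> tuple[Vec, Vec]:
        r = self.radius
        return np.minimum(self.p0, self.p1) - r, np.maximum(self.p0, self.p1) + r

    def transformed(self, rot: np.ndarray, trans: Vec) -> "Capsule":
        return Capsule(rot @ self.p0 + trans, rot @ self.p1 + trans, self.radius)


@dataclass(frozen=True)
class EllipticPlate:
    """Flat elliptical plate: extruded ellipse with an optional through-hole.

    ``axes`` is a 3x3 orthonormal matrix whose rows are (major, minor, normal)
    directions; semi-axes ``a >= b``; total thickness ``thickness`` centred on
    ``center``; ``hole_radius > 0`` drills a circular perforation (along the
    plate normal) through the middle.
    """

    center: Vec
    axes: np.ndarray
    a: float
    b: float
    thickness: float
    hole_radius: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec(self.center))
        axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
            raise ValueError("plate axes must be orthonormal")
        object.__setattr__(self, "axes", axes)
        if not (self.a >= self.b > 0) or self.thickness <= 0:
            raise ValueError("require a >= b > 0 and thickness > 0")
        if self.hole_radius < 0 or self.hole_radius >= self.b:
            if self.hole_radius != 0.0:
                raise ValueError("perforation must lie strictly inside the footplate")

    def contains(self, pts: Vec) -> np.ndarray:
        local = np.einsum("ij,...j->...i", self.axes, pts - self.center)
        x, y, z = local[..., 0], local[..., 1], local[..., 2]
        inside = (
            (np.abs(z) <= self.thickness / 2.0)
            & ((x / self.a) ** 2 + (y / self.b) ** 2 <= 1.0)
        )
        if self.hole_radius > 0:
            inside &= x**2 + y**2 >= self.hole_radius**2
        return inside

    def volume(self) -> float:
        return np.pi * (self.a * self.b - self.hole_radius**2) * self.thickness

    def bbox(self) -> tuple[Vec, Vec]:
        # extent of the oriented plate along each world axis
        half = (
            np.abs(self.axes[0]) * self.a
            + np.abs(self.axes[1]) * self.b
            + np.abs(self.axes[2]) * self.thickness / 2.0
        )
        return self.center - half, self.center + half

    def transformed(self, rot: np.ndarray, trans: Vec) -> "EllipticPlate":
        return EllipticPlate(
            rot @ self.center + trans, self.axes @ rot.T, self.a, self.b,
            self.thickness, self.hole_radius,
        )


Primitive = Sphere | Capsule | EllipticPlate


def union_contains(prims: list, pts: np.ndarray) -> np.ndarray:
    inside = np.zeros(pts.shape[:-1], dtype=bool)
    for p in prims:
        inside |= p.contains(pts)
    return inside


def _bbox_intersection(b1, b2, pad: float = 0.0):
    lo = np.maximum(b1[0], b2[0]) - pad
    hi = np.minimum(b1[1], b2[1]) + pad
    if np.any(lo >= hi):
        return None
    return lo, hi


def _grid_cells_in_boxes(boxes, anchor: Vec, h: float) -> np.ndarray:
    """Deduplicated fine-grid cell indices covering a list of boxes."""
    chunks = []
    for lo, hi in boxes:
        i0 = np.floor((lo - anchor) / h).astype(np.int64)
        i1 = np.ceil((hi - anchor) / h).astype(np.int64)
        ii, jj, kk = np.meshgrid(
            np.arange(i0[0], i1[0]), np.arange(i0[1], i1[1]),
            np.arange(i0[2], i1[2]), indexing="ij",
        )
        chunks.append(np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1))
    if not chunks:
        return np.empty((0, 3), dtype=np.int64)
    cells = np.concatenate(chunks, axis=0)
    return np.unique(cells, axis=0)


def _generic_rotation() -> np.ndarray:
    """Fixed rotation that de-aligns solids from the quadrature lattice.

    Canonical phantom primitives often lie exactly along grid axes; a
    cylinder parallel to the lattice repeats the same 2D quantization error
    in every slice, turning the O(h^2) quadrature error into O(h) with a
    systematic sign. A generic rotation of the lattice restores O(h^2).
    """
    a, b, c = 0.41, 0.23, 0.13  # radians; nothing special, just not aligned
    rx = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
    ry = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]])
    rz = np.array([[np.cos(c), -np.sin(c), 0], [np.sin(c), np.cos(c), 0], [0, 0, 1]])
    return rz @ ry @ rx


def union_volume(prims: list, h: float = 0.02) -> float:
    """Exact primitive volumes minus the grid-quadratured overlap multiplicity."""
    rot = _generic_rotation()
    prims = [p.transformed(rot, np.zeros(3)) for p in prims]
    total = sum(p.volume() for p in prims)
    boxes = []
    for i in range(len(prims)):
        for j in range(i + 1, len(prims)):
            box = _bbox_intersection(prims[i].bbox(), prims[j].bbox(), pad=h)
            if box is not None:
                boxes.append(box)
    if not boxes:
        return float(total)
    anchor = np.min([b[0] for b in boxes], axis=0)
    cells = _grid_cells_in_boxes(boxes, anchor, h)
    pts = anchor + (cells + 0.5) * h
    multiplicity = np.zeros(len(pts), dtype=np.int32)
    for p in prims:
        multiplicity += p.contains(pts)
    excess = multiplicity - (multiplicity >= 1)
    return float(total - excess.sum() * h**3)


def cross_overlap_volume(prims_a: list, prims_b: list, h: float = 0.02) -> float:
    """Volume of union(A) ∩ union(B), quadratured over pairwise bbox overlaps."""
    rot = _generic_rotation()
    prims_a = [p.transformed(rot, np.zeros(3)) for p in prims_a]
    prims_b = [p.transformed(rot, np.zeros(3)) for p in prims_b]
    boxes = []
    for pa in prims_a:
        for pb in prims_b:
            box = _bbox_intersection(pa.bbox(), pb.bbox(), pad=h)
            if box is not None:
                boxes.append(box)
    if not boxes:
        return 0.0
    anchor = np.min([b[0] for b in boxes], axis=0)
    cells = _grid_cells_in_boxes(boxes, anchor, h)
    pts = anchor + (cells + 0.5) * h
    inside = union_contains(prims_a, pts) & union_contains(prims_b, pts)
    return float(inside.sum() * h**3)
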