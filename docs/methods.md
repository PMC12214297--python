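# Methods

`ossimetry` automates 3D morphometry of the middle-ear ossicular chain
(malleus, incus, stapes) from labeled CT volumes. The pipeline mirrors the
workflow used in U-HRCT studies of normal ears: a voxel label map is turned
into refined triangle meshes, anatomical landmarks are detected from
differential-geometric signatures, and twelve clinically reported parameters
are derived — eight landmark distances (mm), the incudostapedial joint angle
(degrees), and the three per-ossicle volumes (mm³). A parametric phantom
generator with closed-form ground truth makes every stage testable without
clinical data. This note records the models, the tunable parameters, the
numerical choices, and what the synthetic tests do and do not demonstrate.

## Coordinate and data conventions

All geometry is computed in millimetre physical space: voxel index `i` maps
to `origin + i * spacing` (voxel-center convention), axes ordered
`(x, y, z) = (L→R, P→A, I→S)`. Label volumes are integer grids, 0 =
background, default labels malleus=1, incus=2, stapes=3 (configurable; the
label encoding of a segmentation is a dataset convention, not a property of
the anatomy). Anisotropic spacings are accepted with a warning; the target
acquisition is 0.1 mm isotropic, and all default tolerances assume that
scale. NIfTI headers store geometry in single precision, so spacing/origin
round-trip to ~1e-7 mm, while voxel data round-trip bit-exactly.

## Surface reconstruction

1. **Signed distance field.** The binary mask (largest 26-connected
   component; discarded islands are logged) becomes a signed Euclidean
   distance field, negative inside, with a half-voxel offset so the zero
   crossing lies on the voxel faces — the unbiased subvoxel boundary
   estimate for center-inclusion rasterization. An isolated single voxel is
   below this representation's resolution: its reconstructed surface is the
   octahedron through the six face midpoints (volume = voxel/6). Features
   spanning ≥ 2–3 voxels are recovered with sub-percent volume error.
2. **Curvature-regularized refinement** (`refine_levelset`): explicit mean-
   curvature flow of the field, clamped after every step to a hard fidelity
   band around the original field (default half the smallest voxel), so the
   interface can never drift farther than the band from the rasterized
   boundary. Zero iterations is the identity; a planar interface is a fixed
   point. The refinement exists for noisy segmentations. It is **off by
   default** (`refine_iterations: 0`): on clean label masks the distance
   field is already subvoxel-accurate, and curvature flow measurably erodes
   the thin stapes crura (≈ 0.22 mm radius loses ~6% of its volume per two
   iterations once the band saturates).
3. **Marching cubes**: the topology-consistent Lewiner variant, yielding
   watertight meshes in physical coordinates (outward orientation enforced
   via the signed volume). On heavily perturbed masks marching cubes can
   emit non-manifold pinch edges (four faces sharing an edge); downstream
   operations therefore require a *closed* surface (every edge borders an
   even number ≥ 2 of faces), which still encloses a well-defined volume,
   rather than strict two-manifoldness. Clean phantom meshes are strictly
   watertight.
4. **Windowed-sinc smoothing**: a Taubin-style low-pass filter — the ideal
   spectral low-pass at normalized cutoff `passband ∈ (0, 2)` is expanded in
   Chebyshev polynomials of the umbrella-weight graph Laplacian, windowed
   with a Hamming window (degree = `smooth_iterations`), and renormalized to
   unit DC gain so the smooth component does not shrink. Defaults: 20
   iterations, passband 0.4. On a clean unit icosphere the volume drift is
   < 0.4%; small passbands (≈ 0.1) additionally attenuate the fundamental
   bending mode of thin tubes (an 8–10-vertex cross-section ring lives at
   eigenvalue ≈ 0.2) and visibly shrink the stapes crura, which is why the
   default passband is 0.4 rather than a more aggressive value.
5. **Volume**: divergence-theorem enclosed volume of the closed mesh.

## Landmark detection

Landmarks use the anatomical lettering A–J: malleus head apex **A**,
lateral-process tip **B**, manubrium tip **C**; incus body top **D**, body
point **E**, short-process tip **F**, long-process tip **G**; stapes head
**G**ₛ, footplate major-axis ends **H**/**J**, footplate point farthest from
the head **I**.

* **Curvature maps.** Gaussian curvature by angle deficit over the Meyer
  mixed Voronoi area; mean curvature from the cotangent-Laplacian
  mean-curvature normal, signed by the outward vertex normal (sphere of
  radius r: K = 1/r², H = +1/r). The raw angle deficits satisfy
  Gauss–Bonnet (Σ = 4π on genus-0 meshes) to rounding error, which the test
  suite uses as a curvature oracle. For *detection thresholds only*, the
  curvature scalars are first diffused by three neighbor-averaging passes:
  voxelization ripple alternates in sign edge-to-edge and cancels, while
  coherent caps and plates survive. Geometry is never altered by this.
* **Farthest point pairs** are exact (the diameter of a point set is
  attained at convex-hull vertices; brute force against the hull candidates,
  lexicographic tie-breaks). Because distance scores are quadratically flat
  around their maximizers, the raw argmax vertex wanders ~2 voxels under
  rasterization noise; every extreme-point landmark is therefore stabilized
  by averaging the near-optimal set (within 0.01 mm of the maximum) and
  projecting the centroid back onto the surface. The refinement is
  deterministic, rotation- and reflection-equivariant, and applied
  symmetrically to both ends of a pair.
* **End assignment** (A vs C, D vs G): the head/body end carries more local
  surface, measured as mesh area within a 0.9 mm ball of each end (robust to
  how bent the ossicle is, unlike a slice perpendicular to a global box
  axis). Ratios below 1.05 are flagged ambiguous and resolved
  lexicographically. When a stapes mesh is available, incus G is instead the
  end nearer the stapes head — the anatomical definition of the joint.
* **Protrusion tips**: connected clusters of convex (H > 0) vertices with
  smoothed K ≥ `min_gauss` (default 4 mm⁻², i.e. tighter than r ≈ 0.5 mm).
  Clusters carrying < 0.05 mm² of area are discarded (noise spikes curve
  tightly but have almost no surface). Within a cluster the tip is the
  support maximizer along the mean normal of the high-curvature core — on a
  capsule this yields the cap apices exactly, which is the property the
  detector is tested against. Tips are non-maximum-suppressed within
  `nms_radius` (0.4 mm).
* **Malleus B** is the most *lateral* tip (largest distance from the A–C
  line) among tips in the central 50% of the principal-axis extent.
  Laterality is the defining property of the lateral process and is far more
  stable under boundary noise than ranking by peak curvature. No tip in the
  band raises a landmark error, mirroring the clinical exclusion of
  incompletely segmented ears.
* **Incus F** is the tip farthest from line DG; **E** maximizes distance to
  F over the body half (vertices beyond the DG midpoint toward D).
* **Stapes footplate**: largest connected near-planar cluster (|H| < 0.5
  mm⁻¹ after scalar smoothing) whose total-least-squares plane fit has RMS
  < 0.08 mm. The footplate *region* is then every vertex within ±0.5 mm of
  that plane, so H, J and I are genuine rim extremes rather than
  flat-face-interior points. H and J are the extreme projections onto the
  PCA major axis of the plane projection; a near-isotropic projection
  (eigenvalue ratio < 1.05) warns that the axis is ambiguous. Perforations
  cannot move H, J or I because all three lie on the rim. G\_s is the vertex
  farthest from the plane on the head side, snapped to the incus
  long-process tip when one is provided.
* The **joint angle** ∠DGI is measured at the incus long-process tip G
  between the rays to D and to the stapes footplate point I, via
  `atan2(|u×v|, u·v)`.

Stapes failures (no planar cluster, reconstruction failure, missing label)
degrade gracefully: GI, HJ, ∠DGI and the stapes volume are flagged
unavailable and everything else is still reported, matching clinical series
where the malleus and incus segment reliably but the stapes often does not.

## Phantoms

Each ossicle is a union of spheres, capsules and (for the stapes) an
elliptical plate, solved so that the target distances are met *exactly* and
every landmark has a closed form:

* **Malleus**: head sphere (r 1.1), neck capsule (r 0.4) to an elbow,
  manubrium capsule (r 0.3) to the tip, and a lateral bump (r 0.28) whose
  apex is landmark B. Given targets (AC, BC, AB) the positions of A, B, C
  are solved from the triangle relations; the elbow is iterated so the bump
  protrudes along the local outward bisector of the bend, making the bump
  apex exactly B and its exposed cap symmetric around the protrusion
  direction. Cap anchors are chosen so the sphere/capsule support points in
  the A–C directions are exactly A and C, and the construction verifies
  that (A, C) is the true diameter of the union.
* **Incus**: body sphere (r 1.3) with long- and short-process capsules
  (r 0.3). A spherical body gives closed forms for D (farthest body point
  from G) and E (farthest from F). F is solved from (EF, FG); both process
  caps are anchored so their apices are exactly G and F.
* **Stapes**: head sphere (r 0.4, laterally offset 0.2 mm so the
  farthest-from-head footplate point I is unique), two straight crura
  capsules (r 0.22), and an elliptical plate (a = HJ/2, b = 0.65 mm,
  thickness 0.3 mm) with optional through-perforation and tilt about the
  plate's minor axis. H/J sit at mid-rim; I is found by a dense rim search
  (closed form when untilted).
* **Chain**: the stapes head apex is placed exactly at incus G, rotated so
  apex→I makes the requested incudostapedial angle with G→D (exact two-step
  rotation: minimal rotation plus a spin that keeps the head as upright as
  possible, so the head stays near-tangent to the incus tip). The malleus
  sits at a fixed offset beside the incus body. Contested voxels at the
  tangent contact go to the incus; the recorded stapes ground-truth volume
  excludes the (≈ 0.003 mm³) contact lens accordingly. A placement error is
  raised if solids overlap beyond 0.02 mm³.

Default dimensions are the automated population means of the modeled study
conditions (AC/BC/AB = 7.91/4.36/4.89, DG/EF/FG = 6.56/4.97/5.55, GI/HJ =
3.25/2.63 mm, angle 96.83°); the randomized suite draws each target from its
published between-ear SD (clipped to ±1.5 SD for constructibility) with a
uniformly random rigid pose per phantom. Radii are fixed at the
anatomically plausible values above.

**Ground-truth volumes.** Union volume = Σ closed-form primitive volumes −
an overlap correction, integrated on a 0.02 mm lattice restricted to the
pairwise bounding-box intersections (outside them no overlap exists, so the
identity is exact up to quadrature in the small overlap lenses). The
lattice is generically rotated relative to the solids: a cylinder parallel
to the grid repeats the same 2D quantization error in every slice, turning
the O(h²) error into a systematically signed O(h); the rotation restores
O(h²) (verified: h = 0.02 vs 0.01 differ by < 0.03%, and the result matches
a 2×10⁷-point Monte-Carlo estimate within its standard error). Volumes are
computed in the canonical frame before any pose, so they are exactly
pose-invariant.

**Rasterization** is center-inclusion (voxel on iff its center is inside).
**Perturbation** flips boundary voxels (6-neighborhood mixes foreground and
background) with a given probability: foreground flips clear, background
flips adopt the majority neighboring label; seeded and reproducible.

### What the phantoms do and do not show

The phantoms have exact landmark ground truth, realistic dimensions and
scale, voxelization noise, pose variation, perforations, tilts and a
boundary-noise harness. They do **not** emulate CT physics (partial volume,
beam hardening, noise texture), segmentation-network error structure,
inter-subject shape variation beyond size jitter, or surrounding anatomy.
Recovery results on phantoms therefore demonstrate the *geometric* validity
of the measurement rules at the stated resolution — not clinical
segmentation accuracy, which is upstream of this package.

## Contour-energy loss

The segmentation stage of the modeled workflow trains with
`0.5·Dice + 0.5·CE + 1e-5·ACE`, where the active-contour term is
∫(α + β·κ²) dℓ along the predicted 0.5-level contour, α = β = 0.1. This
package implements the loss as a standalone, analytically testable
component (network training is out of scope):

* `curvature_field` evaluates the printed per-pixel curvature formula — the
  mean curvature of the graph surface z = u(x, y), with the (1 + uₓ²) terms
  — by central finite differences (one-sided on the boundary ring). It is
  exact for quadratics and O(h²) otherwise.
* `ace_loss` extracts the 0.5-level contour with 2D marching squares and
  integrates α + β·κ² with the trapezoid rule. κ here is the Menger
  (circumcircle) curvature of the contour polyline itself, computed on a
  lightly smoothed copy with an 8-point stencil; the length element comes
  from the raw polyline. Rationale: the loss constrains the contour by its
  own length and bending (the Euler-elastica reading), and the graph-surface
  formula sampled on the contour under-weights κ by a factor ≈ |∇u| ≪ 1 for
  probability-valued fields, while raw per-vertex polyline curvature is
  dominated by marching-squares quantization jitter. With this
  discretization a rasterized disk of radius r reproduces the analytic
  2πr(α + β/r²) within 1.6% for r ∈ {5, 10, 20, 40} px, and the length- and
  curvature-term log-log slopes versus r are +1.01 and −1.04.
* Dice is soft with an ε = 1e-7 smoothing (empty-vs-empty is a perfect
  score); cross-entropy clips probabilities at 1e-7.

## Statistics

The analysis workflow reproduces the replicate-consistency and group-
comparison machinery of the modeled study: ICC(3,1) (two-way mixed,
consistency, single measurement) from the ANOVA decomposition, with
MS_error = 0 short-circuiting to exactly 1; Shapiro–Wilk (α = 0.05) gating
paired t vs Wilcoxon signed-rank, independent t (Welch when Levene rejects
equal variances) vs Mann–Whitney U, and one-way ANOVA (normality +
homogeneity gates) vs Kruskal–Wallis; Pearson χ² goodness of fit for
demographic counts; `mean ± SD` report cells at two decimals with
percentages at one decimal. No multiple-testing correction is applied by
default (a Holm option exists). Null-simulation type-I error of all three
gated procedures is calibrated to [0.035, 0.065] at α = 0.05 over 1000
seeded replicates, and the simulated-ICC recovery (σ_b = 1, σ_e = 0.5,
n = 200 × 3) lands within 0.05 of the theoretical 0.8.

## Problem sizes and reproducibility

The headline benchmark measures 50 randomized noise-free chain phantoms at
0.1 mm voxels (the acquisition resolution the defaults target); the noise-
degradation property uses a 6-phantom × 3-level surrogate of the same
harness, and the statistical calibrations use 1000 replicates — sizes chosen
so the whole suite replays comfortably on a single CPU. Every stochastic
component (phantom draws, perturbations, simulations) is driven by explicit
seeds; identical seeds reproduce results bit for bit, and all outputs embed
the configuration hash and seed.

## Known limitations

* Accuracy constants assume ≈ 0.1 mm isotropic voxels; at coarser spacing
  the generators warn and the detection thresholds (curvature gates, NMS
  radius, footplate band) need rescaling.
* A 10% boundary-flip perturbation erodes ~1 voxel from thin process tips;
  tip-to-tip distances then carry an irreducible ≈ 0.2–0.35 mm bias that no
  detector can recover, because the extremity is absent from the data.
* The level-set refinement trades fidelity for smoothness and should stay
  off for clean masks (see above); it is intended for jagged segmentations.
* Lewiner marching cubes is not exactly mirror-symmetric, so measurements of
  a reflected *volume* agree only to ~3e-3 mm even though the detection
  rules themselves are exactly reflection-equivariant.
* Single-voxel structures reconstruct as inscribed octahedra (volume/6);
  anything the pipeline should measure must span several voxels.
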