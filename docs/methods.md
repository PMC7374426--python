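# Methods

`anthromesh` implements the computational core of a low-cost 3D
anthropometry pipeline: a ring of RGB-D depth cameras is calibrated
extrinsically with a cube marker, the per-camera point clouds are
filtered and fused, and girths, cross-section areas and part volumes are
measured on the reconstructed body mesh by casting fans of coplanar
rays. All lengths are centimeters; axes are right-handed with **y**
vertical (body height), so default measurement sections are horizontal.

## Ray-fan section measurement

A measurement is defined by an oriented circle (center **c**, unit
normal **n**, radius *R*) placed by the operator around the body part;
the circle's size is auto-fitted as 1.2x the farthest point of the exact
section contour, so the contour always lies inside it. `n_rays` origins
are spaced uniformly by angle on the circle and each ray is cast
in-plane toward the center — i.e. perpendicular to the local tangent —
keeping the first mesh intersection.

- **Perimeter** is the length of the closed polyline through the hits in
  angular order. Missed rays are skipped; the closing segment from the
  last hit back to the first is always included, without which the
  measure would not be a girth. For a convex section this is the
  perimeter of an inscribed polygon: it underestimates the true value by
  O(1/n²) and converges from below as the ray count grows.
- **Area** is the fan triangulation about the circle center (the pivot):
  the sum of triangle areas (pivot, pᵢ, pᵢ₊₁) over consecutive hits,
  closing pair included. The decomposition is valid only when the
  section is star-shaped about the pivot; mixed triangle orientations
  are detected and raised as an error rather than silently summed —
  body sections in practice are convex, where the pivot (the section
  centroid) is always interior.
- **Volume** selects a region with a cylinder (base circle swept along
  its normal over a height); the cylinder is cut into slabs of height
  *h* (default 1 cm) and each slab contributes its section area times
  its thickness. Areas are sampled at the slab **mid-height** (midpoint
  rule: exact for prisms, second-order for smooth bodies); when *h*
  does not divide the height the final slab keeps its true, shorter
  thickness so the measured extent is conserved. Slabs with an empty
  section contribute zero and are flagged.

Ray-triangle intersection is a vectorized Möller–Trumbore test with an
inclusive barycentric boundary (ε = 1e-9) so rays that graze shared
edges of axis-aligned faces still register; distance ties resolve to the
lowest face index. Because a fan's rays are coplanar and radial, only
faces whose angular span about the circle center covers the ray's angle
(or its opposite) can be hit; faces are bucketed into 256 angular bins,
which makes the cost per fan essentially linear in the ray count even on
finely tessellated meshes.

Two independent oracles validate the estimators: the exact plane section
(via trimesh's mesh/plane intersection, chained into closed loops) for
perimeter and area, and the divergence-theorem volume for stacked
slices. On the synthetic cubes the estimators at 10⁴ rays agree with
the oracles to better than 0.01%.

## Camera-network calibration from a cube marker

Each camera observes a cube of known edge placed at several positions.
Per capture:

1. **Orthogonal plane fitting.** Point normals (PCA of the 16-NN
   covariance, oriented to the camera) are clustered into up to three
   directional modes (spherical k-means with deterministic farthest-first
   seeding); a sequential 3-point RANSAC plane extraction provides an
   additional, normal-free initialization. Each initialization is
   refined by alternating (a) a regression that projects the per-cluster
   PCA normals onto the nearest orthonormal frame (polar decomposition)
   and refits offsets, with (b) nearest-plane reassignment, until fewer
   than 0.1% of points move (max 50 rounds). Clusters that starve, are
   nearly collinear (edge slivers), or whose points are already explained
   by another plane (an edge band masquerading as a patch) are dropped
   mid-loop. The best state reached is kept, so the recorded residual
   history is non-increasing; a final trimmed refit on well-explained
   points removes stragglers from grazing third faces. The
   lowest-residual converged model wins, preferring more planes on near
   ties. A model is invalid (never an exception) if a cluster has fewer
   than 10 points or the RMS residual exceeds 1 cm.
2. **Cube center.** With three patches, the planes' corner intersection
   stepped half an edge inward along each normal — exact regardless of
   sampling. With two patches, the shared-edge midpoint from the point
   extent along the edge; with one, the in-plane extent midpoints of the
   face. Extent midpoints are exact for fully visible (centrally
   symmetric) faces under any sampling density, but carry a pixel-scale
   quantization floor and are biased when a face is clipped by the image
   border — an extent inconsistent with the known edge length therefore
   rejects the observation.
3. **Alignment.** Matched per-placement centers between two cameras are
   aligned by closed-form Procrustes (Kabsch, proper rotation enforced)
   inside a RANSAC loop (3-point minimal samples, exhaustive when
   feasible, 1 cm inlier tolerance, deterministic seed); scoring is by
   consensus size, then mean inlier distance, plus a mean
   normal-disagreement angle when paired patch normals are supplied.
   After refitting on the consensus, the threshold is tightened to 5x
   the median residual when a markedly better-agreeing subset exists —
   the view-selection step that lets exact corner observations dominate
   quantization-limited ones.
4. **Network assembly.** Cameras are chained per row (Prim-style, edges
   ranked by shared corner-view count, then total shared placements);
   rows are then registered to the reference row through same-mast
   camera pairs with pooled correspondences. Finally a global
   refinement alternates (i) averaging each placement's position in the
   global frame over the corner views of calibrated cameras with (ii)
   refitting every camera to those positions through its own corner
   views — this recovers cameras whose corner views are spread thinly
   across many partners, where pairwise chaining would fall back to
   quantization-limited correspondences. The iteration is a consensus
   scheme with geometric convergence; 150 rounds (or stagnation below
   1e-13) suffice for machine-precision recovery on noiseless sessions.
   Cameras or rows that cannot be connected are reported as
   uncalibrated with a reason, never silently dropped.

The cube-center correspondences only constrain the network when the
marker is seen as a corner (three faces) by enough cameras; the
placement generator therefore tilts the cube by 26–43° about a mostly
horizontal axis so a corner points outward. The marker edge length is a
required input throughout — it is the metric scale of the system.

## Point-cloud preprocessing

Clouds are unorganized, so all neighborhood filters operate on k nearest
neighbors (KD-tree). The chain, in order: depth truncation (drop points
beyond `z_max` along the sensor axis, default 100 cm); median filter
(component-wise median of the 9-NN including self); bilateral filter in
the normal-displacement formulation (each point moves along its normal
by the spatially- and range-weighted mean of its neighbors'
normal-projected offsets; σ_s = 1 cm, σ_r = 0.5 cm — filter parameters
are package choices, chosen at the scale of the sensor noise they
suppress); statistical outlier removal (discard points whose mean 8-NN
distance exceeds the global mean + 1 std of that statistic); normal
estimation (smallest eigenvector of the 16-NN covariance, oriented
toward the sensor). Fusion applies each camera's calibration transform
and concatenates, rotating normals without translating them.

## Synthetic data

The shape generator produces the benchmark objects (cubes of side 15
and 50, cylinders, a cone, a rectangular pyramid) and a capsule body
phantom as watertight meshes, base at height 0. Curved surfaces default
to 4096 facets so tessellation error (O(1/n²), about 10⁻⁷ relative) is
far below the measurement errors being studied. The published 1D/2D
values for the cylinders and cone are inconsistent with circular cross
sections implied by their volumes (e.g. a 200 cm perimeter with a 2500
cm² area matches a 50 cm square, while the volume matches r = 25, h =
50); dimensions here are fixed from the volumes — cylinder 1 (r = 50,
h = 25), cylinder 2 (r = 25, h = 50), cone (r = 25, h = 50), pyramid
base 36 x 12.5 with apex height 60, the unique rectangle consistent
with perimeter 97, area 450 and volume 9000 — and such objects are
flagged `reconstructed_dims` in benchmark output; only the cube rows
are used for numeric comparisons against published estimates.

The depth-camera simulator is a pinhole model casting one ray per pixel
and perturbing the hit distance **along the ray** with zero-mean
Gaussian noise (range noise, matching depth-sensor physics — not
isotropic jitter). It reproduces the geometry of multi-view capture
(perspective sampling density, backface occlusion, frustum clipping,
pixel quantization of silhouettes) but none of the photometric effects
of real sensors: no lens distortion (intrinsics are assumed corrected),
no depth-dependent noise growth, no multi-path or edge artifacts, no
color. Passing calibration tests on these captures therefore
demonstrates the geometric correctness and noise robustness of the
estimators, not performance under real RealSense noise statistics.
Simulated sessions use a two-row, four-mast ring (radius 110 cm, rows
at 75 and 35 cm, 112x84 px, f = 115 px) — a deliberately scaled-down
stand-in for a 13-camera cabin that keeps every cube placement fully
visible to every camera.

## Numerical choices and degenerate inputs

- Orthonormality of fitted frames is exact by construction (SVD); plane
  normals are unit within 1e-9.
- Degenerate (zero-area) mesh faces are dropped at construction with a
  logged count; non-watertight meshes are rejected by the volume oracle
  with their open-edge count.
- A plane tangent to a mesh vertex yields an empty section (degenerate
  loops below 1e-9 total length are suppressed).
- Procrustes refuses collinear or coincident point sets (second
  singular value below 1e-9), where the rotation is unconstrained.
- The benchmark's non-cube rows use the package's own oracles as ground
  truth, so their relative errors measure the ray method alone, not the
  dimension reconstruction.

## Known limitations

- Sections with multiple loops in one plane (both legs at thigh height)
  must be measured one loop at a time; the circle auto-fit selects the
  largest loop.
- Concave sections violate the fan-triangulation assumption and raise
  an error by design.
- Calibration accuracy rests on corner (3-face) marker views; a session
  whose placements never show corners to some camera degrades that
  camera to quantization-limited (~0.1 cm at the default pixel pitch)
  alignment, and the placement generator is tuned to avoid this.
- Surface reconstruction (point cloud to mesh) is out of scope; the
  measurement stage consumes meshes produced by any reconstruction
  method.
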