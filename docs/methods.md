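# Methods

`auriplan` implements the computational geometry behind an AR-assisted
workflow for reconstructing a missing or underdeveloped external ear
(microtia/anotia). The clinical idea: the surgical target — shape *and*
position — is the **specular ear**, the mirror image of the healthy
contralateral ear across the head's midsagittal plane. A patterned cube
fiducial, rigidly attached to the patient through a dental splint, lets a
tablet camera anchor that plan in its own frame during surgery; afterwards,
a surface scan of the outcome is compared quantitatively against the plan.
This note describes each model, its assumptions, the parameters that
matter, and the numerical choices.

## Conventions

All geometry is in millimetres, in a right-handed RAS frame (x = patient
right, y = anterior, z = superior). Loaders accept LPS input (the other
common medical convention) and flip x, y on ingest. Transforms are 4×4
homogeneous matrices acting on column points; `A.compose(B)` applies `B`
first. Reflections are first-class (`kind="reflective"`, det −1); applying
a reflective transform to a mesh flips the face winding so the
outward-normal convention (positive divergence-theorem volume for closed
meshes) is preserved. The **axial axis** is the superior–inferior z axis;
"axial rotation" means twist about it.

## Midsagittal plane by mirror-ICP

The plane is the minimiser of the symmetric mirror-registration residual:
reflect a vertex subsample across a candidate plane, rigidly register the
reflection back onto the head by ICP, and compose the reflection with the
registration. The composition is a near-reflection; its fixed plane is
extracted from the −1 eigendirection of the symmetrised linear part
(offset = n·b/2) and becomes the next candidate. Iteration stops when the
plane moves by < 0.01° and < 0.01 mm (max 50 outer iterations; failure
raises an error carrying the last residual).

Initialisation: the perpendicular bisector of a left/right landmark pair
(eyes, ears, canthi) when available, then a plane through midline
landmarks, then the least-variance principal axis of the vertex cloud
through the centroid. The subsample is `min(5000, n)` vertices drawn with
a caller-supplied seed, so results are reproducible. Trimming in the inner
ICP (80th percentile kept) makes the estimate robust to unilateral
asymmetry: on synthetic heads with one ear removed entirely, the plane
stays within a fraction of a degree of truth, because the missing-ear
residuals fall in the rejected tail.

## Rigid registration

`rigid_from_correspondences` is the weighted closed-form (Kabsch/SVD)
solve. Reflections are excluded by construction: when det(VUᵀ) < 0 the
smallest singular direction is negated. Configurations whose second
singular value vanishes (collinear points) are rejected rather than
silently returning one of infinitely many optima.

`icp` registers source vertices onto a target *surface*: correspondences
are exact foot points on the target triangles (see below), the worst
residuals above the `reject_percentile` (default 90) are dropped, and each
iteration takes a linearised **point-to-plane** Gauss–Newton step. The
point-to-plane objective is used deliberately: point-to-point update steps
slide tangentially on smooth anatomy and converge far too slowly to be
useful on head surfaces (degrees of residual rotation after hundreds of
iterations), whereas the point-to-plane linearisation converges in a
handful of iterations to machine precision on the same inputs. The
reported rms is always the true point-to-surface distance rms, enforced
non-increasing: a step that raises it is rolled back and iteration stops
(`tol_mm` = 1e-4 by default, max 100 iterations).

Masked registration ("align on the most similar surfaces") selects source
vertices inside a union of spheres (default radius 25 mm) centred on named
landmarks — eyes, forehead, nose — so that regions deformed by surgery,
swelling or facial expression do not bias the alignment.

## Closest-point queries

Point-to-surface distances use an exact two-stage query: a k-d tree over
triangle centroids yields an upper bound (exact distance to the triangle
owning the nearest centroid), then every triangle whose centroid lies
within `bound + r_max` is tested exactly (`r_max` = largest
centroid-to-corner distance of the mesh). No true minimiser can be missed.
The per-triangle test is the standard barycentric-region classification,
vectorised. Zero-area faces — present in real scanner exports — are
retained in the mesh but flagged and excluded from queries. Ties between
exactly equidistant faces resolve to the lowest face index, for
determinism.

## Signed distance maps and summaries

For each test-mesh vertex the map stores the distance to its foot point on
the reference surface, signed by the nearest reference face's outward
normal: **positive = outside the reference**, so a uniformly enlarged
(e.g. swollen) ear reads positive. The headline direction is postop →
plan (the plan defines the sign); the reverse map is also emitted. The
summary reports mean and SD of *absolute* values (population SD), the
signed mean, and the signed min/max. Region summaries re-aggregate the
per-vertex values inside landmark-centred spheres; a sphere capturing no
vertices yields a flagged null rather than an error, since region
dictionaries are often reused across cases.

## Ear morphometrics

Length is the 3D caliper diameter — the maximum pairwise vertex distance,
computed exactly on the convex-hull vertices. Width needs a convention,
because "the shortest metric in the perpendicular direction" is ambiguous:
the default takes the single direction orthogonal to the length axis that
lies in the ear's least-squares best-fit plane (the standard auricular
width), and `width_mode="min_perpendicular"` instead minimises the extent
over all directions orthogonal to the length axis. Both are rigid
invariant; the reported axes are exactly orthogonal.

## AR guidance chain

The camera is a pinhole with optional two-term radial distortion. The cube
marker (default side 30 mm) has a fixed corner convention — per face,
counter-clockwise viewed from outside, starting at the face's +u+v corner
— so synthetic observations are well defined. Pattern detection is out of
scope; the interface is `(face id, corner index, pixel)` observations.

The pose solve initialises from a planar homography (DLT) on the
most-observed face, decomposed to a rotation and translation with the
cheirality constraint t_z > 0, then refines all six pose parameters by
Gauss–Newton with Levenberg damping on the pixel reprojection error
(λ starts at 1e-3, ×10 on a rejected step, ÷10 on an accepted one, stop at
Δrms < 1e-10 px or 100 iterations). Only improving steps are accepted, so
refinement never worsens the initialisation. Noiseless synthetic
observations are recovered to ~1e-13 px rms. Note the classic planar-pose
caveat: a single frontal face constrains tilt weakly (degree-level errors
at 0.5 px noise), while a corner-on view with three visible faces is
well-conditioned (~0.15° median at the same noise).

The guidance composition is
`T_cam←earplan = T_cam←marker · T_marker←splint · T_splint←head · T_head←earplan`,
all rigid. Tracking status is "tracked" (green frame) iff the marker is
visible and the reprojection rms is ≤ the threshold (inclusive; default
2 px). The silhouette check projects a mesh under two poses, takes the 2D
convex hulls, samples both contours at matched polar angles about their
centroids, and returns the mean matched-pair distance — this reproduces
the intuitive fx·Δx/z pixel shift for a lateral offset, which a
nearest-point contour metric would systematically underestimate (factor
~2/π for convex silhouettes).

## Synthetic data

The generator exists so every stage is testable offline with exact ground
truth. A head is a radially displaced UV-sphere: an ellipsoid (default
semi-axes 75 × 95 × 110 mm, a typical adult head) plus Gaussian angular
bumps for nose (18 mm), brow (6 mm), chin (8 mm) and eyes (3 mm) — the
features masked ICP locks onto — and a parametric ear on each side:
an elliptical protrusion (height 60, width 30, protrusion 12 mm) carrying
a helix-like ridge (6 mm) on an elliptical annulus. All displacement
fields depend on |x|, and the longitude grid is constructed exactly
symmetric under x → −x (mirror partners share the same float values with
the sign of x negated exactly), so the right ear is the mirror image of
the left **to the last bit** and the midsagittal plane x = 0 is exact
ground truth. Default tessellation is 64 × 88 (≈5.5 k vertices), enough
for sub-0.2° registration while keeping the full test suite fast.

Microtia cases zero the ear displacement field on one side, which removes
the ear and leaves a smooth closed cap; the healthy side is bit-identical
to the input head. Postoperative scans move the ear-region vertices by a
stated rotation/translation/scale about the region centroid (limits:
|angle| ≤ 30°, scale 0.8–1.3), blended with a cosine ramp over the outer
20 % of the crop radius to avoid crease artefacts that would dominate
distance maps, plus independent Gaussian vertex noise everywhere. Marker
scenes back-face cull cube faces against the view ray and add Gaussian
pixel noise. Every generator is byte-deterministic under a fixed seed.

What the generator does **not** emulate: scanner artefacts (holes,
topological noise, non-uniform sampling), skin deformation, texture, and
real anatomical ear structure. Passing tests therefore demonstrate the
correctness of the geometry pipeline under controlled conditions, not
clinical accuracy on real scans.

## Evaluation pipeline and parameter recovery

`compare_to_plan` chains: masked ICP (stable facial regions) → signed
distance map (both directions) → optional region summaries → ear-crop
morphometrics (differences are postop − plan) → residual ear pose. The
residual pose registers the inner 80 % of the postop ear crop (avoiding
the blend zone) onto a slightly wider plan ear crop and reports the
rigid transform plus its axial twist via a swing–twist quaternion
decomposition. On 50 seeded synthetic scans with 2–10° axial rotations and
0.3 mm vertex noise the median absolute angle error is ≈0.2°, and the
signed map shows the expected opposite-signed anterior/posterior lobes.

## Benchmark runner

`run_benchmark` discovers a deposited-model directory by configurable
glob patterns (plan, postoperative scan, phantom reference, per-experiment
placed-ear crops, optional landmarks), auto-checks the RAS/LPS hypothesis
by registering under both and keeping the lower-rms one, and recomputes:
the pooled simulation-scenario statistic (placed ears vs phantom
reference; placement error is the measurand, so crops are *not*
re-registered by default), the ear shape statistic (ear-to-ear
registration first, so position error is removed), the positioning
statistic (masked head registration, so ear shape *and* position errors
remain), and ear length/width differences. A configurable tolerance gate
(default ±0.3 mm, absorbing unknown upstream alignment settings) compares
each statistic against expected reference values when provided. The
repository ships no clinical scans; tests exercise the runner on a
generated stand-in directory (files prefixed `synthetic_`) whose ground
truth is known.

## Known limitations

- Rigid registration only; real postoperative soft tissue deforms.
- The width convention affects morphometric differences at the
  millimetre level; both readings are available but only one is reported
  at a time.
- Plane estimation assumes the head is the dominant symmetric structure
  in the mesh; scans containing shoulders or headrests should be cropped
  first.
- Single-face marker views are intrinsically tilt-ambiguous at realistic
  pixel noise; guidance accuracy claims should be read against multi-face
  tracking.
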