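# Methods

## Coordinate conventions

All coordinates are right-handed millimetres. Ultrasound slices use pixel
(0, 0) at the left-bottom corner, in-plane axes u (right) / v (up), and an
out-of-plane coordinate of 0; the slice calibration T_C and the tracking
transform T_T chain a pixel into tracker space as `z = T_T · T_C · x`. All
transforms are proper rigid (orthonormal rotation with determinant +1 plus
translation); homogeneous 4×4 matrices appear only at the serialization
boundary. Angles in configuration and on the CLI are degrees; the internal
axis-angle parameterization is radians.

## Registration model

The registration estimates the rigid map T_R from the preoperative MR space
to the intraoperative tracker space. The guidance section titles this step an
"affine" alignment, but the optimized degrees of freedom are translation and
rotation only, and the constraint bounds are stated only for those, so the
implementation is rigid; kidney deformation is handled upstream by gating all
slices at end-exhale rather than by extra transform freedom.

**Initialization.** Three paired landmarks (cranial end, caudal end, kidney
hilum) give T_0 by the closed-form least-squares rigid fit (SVD with
determinant correction, no scaling). Collinear or duplicated triples raise a
degeneracy error.

**Objective.** With K_US the kidney contour points from all four slices and
V_US the vessel points from the transverse pair, both in tracker space, the
objective is the categorized mean squared closest-point distance

    MSE(T) = (1/K2) Σ d(k_i, T·kidney)² + (1/V2) Σ d(v_i, T·vessels)²

i.e. each category contributes the *mean* of its squared distances, so a
handful of vessel points carries the same weight as the larger kidney set.
When V2 = 0 the vessel term is dropped. Distances are Euclidean point-to-
surface distances; correspondences are formed by carrying the features into
MR space with the current T⁻¹ and querying the (static) MR meshes, which lets
the closest-point acceleration structures be built once.

**Constrained update.** Writing the current estimate as T = D ∘ T_0, the
feasible set is ‖rotvec(D)‖ ≤ α and ‖trans(D)‖ ≤ A, *cumulative* offsets
relative to the initialization rather than per-iteration increments: the
stated premise of the bounds is that the landmark initialization is already
fine, which caps the total excursion. Each iteration solves the weighted
closed-form rigid fit on the current correspondences; if the fit is feasible
it is exact and accepted. Otherwise it is projected onto the feasible set
(axis-angle rescaled to α, translation offset clipped to norm A) and refined
by one bounded SLSQP pass over the six offset parameters; the best feasible
candidate is accepted only if it does not increase the correspondence MSE,
otherwise the previous estimate is kept. Because the accepted update never
increases the MSE at the old correspondences, and re-matching can only
shorten per-point distances, the recorded MSE trace is non-increasing — the
property the stopping rule presumes.

**Stopping.** Iteration ends when the absolute MSE decrease falls below h
(default 0.1 mm², the clinical operating value) or after n_max = 200
iterations (unspecified in the source protocol; 200 comfortably exceeds the
few-to-tens of iterations observed). h is interpreted as an absolute decrease
in mm²; it is configurable, and convergence-style tests use a tight h since
the operating default is a speed/accuracy compromise, not a convergence
criterion.

**Directions.** The optimized and reported transform T_R maps MR → tracker
(it acts on the preoperative models and the plan); the inverse, exposed as
`RegistrationResult.tracker_to_mr`, is the direction that composes with the
calibration chain to carry ultrasound pixels into MR space.

## Closest-point queries

Point-to-mesh queries use exact point-to-triangle projection on a candidate
set prefiltered by two KD-trees: the distance to the nearest vertex bounds
the optimum from above, and faces whose centroid-distance-minus-circumradius
exceeds that bound cannot win, so the result equals exhaustive minimization
over all triangles. Ties within 1e-12 mm are broken by the lowest face index,
making results reproducible across query orders. The test suite checks
equality against an independent scalar all-triangles oracle.

## Respiratory gating

Gating is batch selection over an acquired window (the protocol buffers
50–100 slices at 20/s): the slice minimizing the marker-centroid-to-axis
distance is the end-exhale slice, ties broken by the earliest index. No
streaming or predictive detection is attempted; intraoperative puncture
timing is a human decision supported by the plotted trace.

## Synthetic scenes

The generator stands in for volunteer/phantom acquisitions and defines the
study conditions:

- **Kidney**: superellipsoid (exponent 2.5) with semi-axes 55 (cranio-caudal)
  × 30 (medial) × 25 (anterior) mm and a cylindrical notch of radius 12 mm
  carved from the medial face, meshed watertight by marching cubes on the
  implicit field at 2.5 mm grid resolution. The notch makes the hilum
  landmark geometrically identifiable and breaks rotational symmetry the way
  a real hilum does.
- **Vessels**: capped tubes — a near-vertical IVC (radius 8 mm) 27 mm medial
  of the kidney and a hilum vein (radius 4 mm) running from the IVC into the
  notch.
- **Slices**: two transverse planes (normals within 4° of the long axis,
  ±8 mm about the kidney centroid) and two longitudinal planes (normals
  within 4° of the anterior axis, ±5 mm), so any transverse/longitudinal
  normal pair is within 8° of perpendicular. Feature points are arc-length
  samples of the plane/mesh intersection curves of the truth-transformed
  surfaces: kidney points from all four slices (default K2 = 24, ~6 per
  slice), vessel points from the transverse pair only (default V2 = 10).
  These defaults are somewhat richer than the 8–15 points reported for the
  rigid-phantom protocol because synthetic contours are complete, whereas a
  scientist picking points in real slices concentrates them where contrast
  allows.
- **Noise**: isotropic Gaussian, 1 mm sd on feature points (picking error in
  the slices is not quantified in the source; 1 mm ≈ one B-mode pixel at
  typical abdominal depth) and 2 mm sd on landmarks (manual selection of
  anatomically extended structures is coarser).
- **Truth motion**: axis-angle rotation plus translation, drawn within a
  stated fraction of the constraint bounds A = 28 mm / α = 30° (recovery
  studies use half the bounds, matching the premise that initialization is
  approximately right).
- **Breathing trace**: raised-cosine distance waveform (period 4 s ≈ 15
  breaths/min, amplitude 10 mm, 1 mm baseline) with optional drift and
  jitter, sampled at 20/s and clipped at zero.

What the generator does *not* emulate: B-mode image formation (speckle,
shadowing, contrast dropout), kidney deformation between slices, operator-
dependent point placement bias, or inter-subject anatomical variability.
Passing recovery tests therefore demonstrate correctness of the geometry and
optimization under the stated noise model, not clinical accuracy on humans;
the human-study mean accuracy (3.53 mm RMS TRE) is used only as a contextual
upper tolerance for the noisy-recovery median.

## Planning

Vessel segmentation is a connected-threshold region grow: the union of
connected components of the [low, high] intensity band containing the seeds.
Connectivity is 6 (faces) by default, configurable to 26; the band is
two-sided as the general form of an intensity-threshold rule. Masks are
smoothed with a 3D Gaussian (sd in mm, converted to voxels per axis),
zero-padded, and meshed by marching cubes at level 0.5, so the surface is
closed; vertices are returned in physical coordinates. Kidney and skin
segmentation are manual in the source workflow and are not implemented —
synthetic or user-supplied meshes stand in. Trajectory clearance is the
minimum distance from the entry–target segment to the vessel surface,
computed by a segment-crossing test (vectorized Möller–Trumbore ray casting)
followed by dense sampling plus bounded 1-D refinement of the continuous
distance-along-segment function; an intersecting or embedded segment scores
0.

## Evaluation

RMS TRE is the root mean square distance between the two mappings of an
evaluation point set, by default the kidney-mesh vertices (the volumetric
"all voxels in the kidney" variant differs only in weighting the interior;
vertices are the natural choice for mesh-based scenes). The repeatability SD
maps every evaluation point by every repeated registration and pools the
squared deviations from the per-point mean over both points and repetitions
— pooling over both is the symmetric reading of "RMS distance from the
transformed positions to their average". The recovery study draws a fresh
scene per repetition seed, re-registers with independently re-drawn landmark
noise, and reports per-scene TRE plus the pooled SD, mirroring a
multi-operator protocol with the operator replaced by the landmark-noise
draw.

## Numerical choices and limitations

- Transform validation tolerates 1e-8 orthonormality error on input;
  composed products stay orthonormal to machine precision over the iteration
  counts used here.
- The constrained update accepts a candidate only on strict improvement
  (margin 1e-15), so a stalled iteration returns the previous transform and
  the stopping rule fires on the resulting zero decrease.
- Problem sizes in the test suite and acceptance script (kidney meshes at
  2.5 mm resolution ≈ 8k faces; 20–50 scenes per study; 1000 scenes for the
  monotonicity/feasibility sweep) were chosen so a full run completes in a
  few minutes on one CPU while leaving the statistics stable across seeds.
- Known limitations: rigid-only motion model; no intensity-based fallback
  when feature picking fails; the containment/ray tests assume closed
  meshes; `trajectory_clearance` is exact only up to the sampling/refinement
  resolution (validated against a dense-sampling oracle to ~0.01 mm).
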