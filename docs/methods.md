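# Methods

This note documents the models, conventions and numerical choices behind
`phf3d`, what the synthetic test bed does and does not emulate, and the
design decisions taken where the problem left genuine freedom.

## 1. Coordinate conventions and the anatomical frame

All lengths are millimetres, all serialized angles degrees (radians are
internal only).  The humeral reference frame is built on the pre-fracture
blueprint in five steps:

1. **axial** — direction of the least-squares infinite cylinder fit to
   the diaphysis, sign-resolved to point proximally (toward the neck
   landmark centroid);
2. the **anatomical-neck plane** — total-least-squares plane through the
   neck landmarks (10 points recommended);
3. **anatneck** — the plane normal, sign-resolved "toward the glenoid"
   by an explicit `glenoid_hint` vector (any vector with a positive dot
   product with the true medial direction).  The hint is an argument
   because the package never segments the scapula; a hint nearly
   orthogonal to the neck normal (|dot| < 0.1) raises an
   ambiguous-orientation error rather than guessing;
4. **coro** = axial × anatneck, normalized;
5. **sag** = axial × coro, normalized.

Each named axis is interpreted as the **normal of its named plane**:
varus/valgus is rotation about `coro`, anterior/posterior tilt about
`sag`, anteversion/retroversion about `axial`.  This is the only reading
under which `coro` (an antero-posterior direction on a right humerus) is
consistent with varus/valgus living in the coronal plane.

The origin **O** is the center of the sphere fit to blueprint vertices on
the articular side of the neck plane (default margin 1 mm, configurable).

**Side handling.**  Frames are built intrinsically from the bone, so the
triad is chirality-dependent: on a left humerus `coro` points anteriorly
while `sag` points laterally on both sides.  Mirror conjugation of
rotations shows that reflecting the anatomy flips the handedness of
twists about the axial and sagittal axes but not about the coronal axis;
the sign table `SIDE_TWIST_SIGNS` therefore multiplies (coronal,
sagittal, axial) twists by (+1, +1, +1) on the right and (+1, −1, −1) on
the left, making the clinical positives — varus, posterior tilt,
retroversion — side-consistent.  Tests verify this by mirroring a
displaced humerus and checking that all reported signs survive.

**Morphometry definitions** (the literature does not fix formulas, so
they are frozen here):

* *inclination*: the clinical neck-shaft angle, i.e. 180° minus the angle
  between `axial` (proximal) and `anatneck`; normal anatomy ≈ 135°;
* *retroversion*: signed axial-plane angle from the neck-reference
  direction to the `anatneck` projection, positive posterior.  The
  reference direction is the bicipital-groove direction rotated about
  `axial` by a conventional +60° (the groove sits ≈ 60° anterior of the
  medial reference axis); the constant is configurable and applied
  side-aware;
* *radius of curvature*: radius of the head sphere;
* *head height*: head-sphere radius minus the distance from O to the
  neck plane (the height of the articular cap, ≈ 17.8 mm at defaults);
* *posterior / medial offsets*: components of (O − nearest point on the
  diaphyseal axis) along the side-consistent posterior and medial
  directions.

## 2. Displacement decomposition

The reduction transform *M* maps a fragment from its displaced (injury)
pose to its anatomic pose; rigidity (RᵀR = I, det R = +1, exact
homogeneous bottom row) is validated on construction and any scaling or
reflection raises an error.

*Translation*: G_P = area-weighted surface centroid of the displaced
fragment, G_R = M·G_P; the report carries the 3D norm and the unsigned
norms of the vector's projections onto the three reference planes (plus
signed per-axis components, for transparency about the projection-vs-
component distinction).  Surface centroids are used because fragments are
open shells for which volume centroids are undefined; a volume-centroid
option exists for closed meshes.

*Rotation*: axis–angle of the displacement rotation, with the angle in
[0°, 180°] (axis (0,0,1) by convention at zero).  Per-plane clinical
angles are the **swing–twist** decompositions about each frame axis —
independent twists rather than a sequential Euler chain, because no
rotation order is clinically defined and independent twists are
order-free and match the reading of "rotation in the coronal plane".
The twist of R about unit axis a uses the closed form
θ = atan2(a·vex(R − Rᵀ), tr R − aᵀRa), which equals the quaternion
projection onto the twist axis; the test suite cross-checks against an
independently coded quaternion oracle to 10⁻⁶ degrees.  Because clinical
angles describe the *displacement* while *M* encodes the correcting path,
twists are extracted from R_Mᵀ (twist of an inverse is the negated
twist); a head displaced 30° into varus thus reports +30°.

Each per-plane twist magnitude is bounded by the 3D rotation angle, and
each in-plane projection by the 3D translation norm — the mathematical
content of the finding that 2D measurements systematically underestimate
3D displacement.  The cohort summary quantifies this with a paired t-test
of 3D norm vs 2D projection per plane (mean difference, 95% t-CI).

## 3. Neer criteria and bins

A fragment is displaced at **≥ 10 mm** 3D translation or **≥ 45°** of
rotation in any single reference plane; both thresholds inclusive.
Part count = 1 + number of displaced fragments, capped at 4.  Reporting
bins: translation {<5, 5–9.9, ≥10} mm and fine bins {<5, 5–9, 10–15,
>15} mm (binning is on the raw value — 9.95 mm stays in 5–9.9; display
rounding is separate; 15 mm belongs to 10–15); per-plane rotation
classes {>45 negative, 5–45 negative, <5, 5–45 positive, >45 positive}
with 5° and 45° inclusive toward the larger class.  The brute-force
threshold rule is re-evaluated in tests over a >10⁴-point grid that
includes every boundary value, and monotonicity (growing a displacement
never un-displaces it) is property-checked.

## 4. Statistical shape model

A PCA model over densely corresponded meshes: mean vertex coordinates
plus orthonormal modes of the centered vertex matrix (thin SVD), with
non-increasing variances.  `variance_to_retain` defaults to 0.98.
Prediction from a shaft segment:

1. the observation must span ≥ 40 mm along its principal axis (the
   clinical method uses 6 cm; shorter stubs raise a prediction-failure
   error, mirroring cases where no blueprint can be generated);
2. rigid (Kabsch) alignment of the observation onto the corresponding
   model vertices — rigid only, never similarity, honoring the
   no-resizing constraint on all transforms;
3. ridge solution for mode coefficients: ‖Ac − b‖² + λ Σ(cᵢ/σᵢ)², with
   the penalty in units of per-mode standard deviations and λ = 1 by
   default.  At λ = 0 the minimum-norm least-squares solution is used so
   modes without expression in the observed region cannot blow up;
4. the prediction is returned posed in the observation's coordinates,
   with the shaft-region RMS residual as the main diagnostic.

Correspondence is by construction for synthetic meshes; registering
clinical meshes onto the model topology is the documented integration
point for a clinically trained model and is out of scope.

## 5. Reduction by registration

The clinical reduction step is manual; automating it by **trimmed
point-to-plane ICP** is this package's principal methodological
substitution, and `accept_manual_transform` preserves the manual
workflow for externally produced transforms.  Details:

* correspondences are nearest target-surface samples (KD-tree over
  blueprint vertices with outward vertex normals; point-to-tangent-plane
  distances);
* each iteration keeps the best `trim_fraction` of correspondences
  (default 0.7 — real fracture surfaces have no blueprint counterpart
  and must be discardable) and solves the linearized 6-dof update;
* convergence at relative residual change < 10⁻⁶ or 200 iterations;
  non-convergence is reported in the result, never raised;
* with no initial transform, a multi-start over the 24 octahedral
  rotations about the fragment centroid is scored by a short coarse ICP;
  candidates are ranked by *near-untrimmed* (95%-keep) residual — a
  mis-rotated pose of a locally symmetric fragment can look good under
  heavy trimming but not once the distinctive regions count — and the
  leading three are refined fully, ties broken toward the smaller start
  rotation.  Results are deterministic given settings and seed;
* fragments below 50 vertices or 195 mm² of surface area are rejected
  (surface registration of slivers is unreliable).

Ground-truth recovery studies on synthetic fractures use
`trim_fraction = 0.95`: synthetic fragments are cut from the intact
surface and carry no fracture-surface outliers, so nearly all
correspondences are informative, and heavy trimming would discard
exactly the tuberosity-bump points that disambiguate the nearly
spherical head.  The 0.7 default remains the right choice for fragments
with genuine off-blueprint surface.

**Blueprint positioning.**  Shaft-anchored mode registers the
blueprint's anchoring region — the shaft *plus the lower metaphyseal
flare* — onto the observed shaft.  The flare matters: an open
cylindrical tube is invariant under axial slide and nearly invariant
under spin, so a shaft-only registration is ill-posed; the flare locks
the axial station and the bicipital groove locks the spin (a multi-start
over 45° axial spins guards the groove lock-in).  Initialization aligns
the two least-squares cylinder axes.  Registration RMS above `max_rms`
(default 2 mm) raises a positioning failure.  Pose-anchored mode places
the blueprint relative to a user-supplied abstract glenoid frame at 0°
flexion, neutral rotation, 30° abduction (all overridable); the scapula
is never required.

## 6. The synthetic humerus

The generator emulates the geometry the measurement pipeline consumes:
a watertight ring-lattice surface comprising a cylindrical diaphysis
(radius 12 mm, length ≥ 80 mm) with a shallow bicipital-groove sulcus, a
metaphysis blending into the anatomical-neck rim with greater- and
lesser-tuberosity prominences, and a spherical articular cap (radius
24 mm) bounded by the neck plane (cap half-angle 75°).  Default anatomy:
inclination 135°, retroversion 20°, medial offset 6.5 mm, posterior
offset 2.5 mm — typical adult values.  Head-center offsets are defined
in the frame's own coronal/sagittal basis so morphometry round-trips
exactly.  The groove modulation has its mean and first circular harmonic
removed: the sulcus survives (it is what locks azimuth in
registrations) while least-squares cylinder fits keep the nominal axis
and radius unbiased.

Landmarks are exact by construction: 10 neck points on the rim circle,
groove points on the shaft surface, the head center, and the full
construction frame.  Topology depends only on resolution, so meshes of a
population are densely corresponded by construction.

**Populations.**  Parameters are drawn normally around the defaults
(σ: head radius 2 mm, inclination 5°, retroversion 8°, offsets 1–1.5 mm,
shaft radius 1 mm; invalid draws are resampled).  Two deliberate design
choices make the population a fair test of shaft-based prediction:

* *diaphyseal signatures*: each head parameter leaves a small (~0.3 mm
  per SD), distinct trace on the shaft — a proximal taper for head size
  and mutually orthogonal circumferential harmonics for the others —
  emulating the anatomical covariation that makes the clinical SSM work.
  Harmonics of order ≥ 2 with zero mean leave cylinder fits unbiased;
* *linear shape space* (default for SSM training stock): vertices are
  drawn from the tangent space of the generator at the base anatomy
  (first-order expansion), so the population spans exactly the
  low-dimensional linear space PCA assumes.  Landmarks come from the
  exact generator at the drawn parameters and agree with the linearized
  vertices to second order in the dispersions.  `linearize=False` gives
  exact nonlinear meshes (used for morphometry Monte-Carlo checks and
  ground-truth recovery studies).

Because the default six-factor population is exactly rank-6, retaining
98% of variance can drop the weakest genuine factor entirely — an
artifact of the low-dimensional synthetic world, where real training
sets have smoothly decaying spectra.  Shape-model verification therefore
builds its models with full variance retention; the 0.98 default stands
for realistic use.

**Fractures.**  Fragments are cut along bands of the ring lattice
(surgical-neck cut at metaphysis parameter 0.25 by default; tuberosity
fragments as azimuthal windows over the bump regions): smooth analytic
regions, not irregular fracture lines — sufficient for
transform-recovery testing and a stated realism limitation.  Fragments
are open shells; each is displaced by a rotation about its own anatomic
centroid plus a translation, optional i.i.d. Gaussian vertex jitter is
added afterwards, and the exact noise-free reduction is stored as ground
truth (displacement ∘ reduction = identity to machine precision).

**Cohorts.**  Fracture lines are Bernoulli draws (surgical neck 0.90,
greater tuberosity 0.91, lesser tuberosity 0.44); head rotation is drawn
per plane (coronal N(2°, 25°) — varus-skewed with a few percent beyond
45°; sagittal N(10°, 17°) posterior-skewed; axial N(8°, 24°)
retroversion-skewed) and tuberosity translation components are isotropic
normal (σ 5.5 / 6.5 mm).  These are configuration data, not code
constants, shaped loosely like clinically observed frequencies; cohort
statistics on them are qualitative reproductions, not clinical claims.

## 7. Problem sizes and verification scales

Unit and property tests run at azimuthal resolution 24–36 (≈ 900–1 900
vertices), chosen as the coarsest scale at which all geometric
round-trips hold comfortably within their tolerances.  The end-to-end
studies use 200 seeded fractures over 20 anatomies for ground-truth
recovery, a 30-member training population with 100 held-out predictions
for the shape model, 77-case cohorts for the summary statistics, and
10³–10⁴ randomized instances for the frame, projection and Neer
property checks.  `scripts/acceptance.py` re-runs all of these from a
single seed.

## 8. What passing tests do and do not show

Passing tests demonstrate that the measurement chain — frame
construction, rigid decomposition, per-plane angles, Neer logic,
registration, and SSM fitting — is internally correct, equivariant, and
recovers known ground truth under the stated synthetic conditions.  They
do not validate: manual CT segmentation quality; SSM accuracy on real
anatomy (the synthetic shape space has built-in, exactly linear
covariation, and reported prediction errors are for this synthetic model
only); ICP behaviour on real fracture surfaces with comminution or
segmentation noise beyond i.i.d. jitter; or the clinical cohort
percentages, which depend on patient data this package does not contain.

## 9. Known limitations

* Fragment cuts are smooth parametric regions; no comminution,
  edge-to-edge matching is deliberately not attempted.
* Vertex noise is i.i.d. Gaussian; correlated imaging/segmentation
  artifacts are not modelled.
* The groove-referenced retroversion constant (60°) is a convention,
  configurable but not individually calibrated.
* Pose-anchored positioning exposes pose parameters rather than encoding
  a rule for restoring the joint space, which is subjective in practice.
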