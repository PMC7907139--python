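# Methods

## The system being simulated

An AR arthroscopy rig consists of: an optical pose tracker whose stereo
head watches fiducial markers; a base plate rigidly attached to the
anatomy (or phantom) carrying one marker that *defines* the model base
frame Σ_M; an oblique-viewing arthroscope carrying a marker on its camera
head (frame Σ_A) and a second marker on the rotatable lens cylinder; and a
renderer that projects preoperative organ meshes into the scope's view.
`scopesight` replaces every hardware element with a parametric simulation
and keeps the computational chain identical, so chain correctness can be
asserted exactly (zero noise in → zero overlay error out) and error
behaviour can be studied as a function of each noise source.

## Transforms and conventions

Transforms are rotation + translation pairs (equivalently 4×4 homogeneous
matrices), column-vector convention, pre-multiplication: `p' = R p + t`.
Every transform carries `from_frame`/`to_frame` labels and composition
refuses chains whose labels do not meet. Units are millimetres throughout;
angles are degrees at all public interfaces and radians only inside
function bodies. The per-frame registration chain is

    model → camera  =  C(θ) ∘ T_AT ∘ T_sA⁻¹ ∘ T_sM

with `T_sM : Σ_M → sensor` and `T_sA : Σ_A → sensor` the tracked poses,
`T_AT : Σ_A → tip` the fixed mount measured once per session, and `C(θ)`
the tip → camera-sight transform of the oblique lens. The chain order is
fixed by requiring that each link maps the frame the previous link ends
in; it is verified two independent ways (a step-by-step frame-hopping
oracle, and zero-noise end-to-end exactness) rather than by matching any
printed formula.

The rigid point-set fit (`absolute_orientation`) is the closed-form SVD
solution with a reflection guard (the smallest singular direction is
flipped when the unconstrained optimum is improper), returning the RMS
residual in mm. Inputs with fewer than three points or a collinear source
set raise a degenerate-geometry error; planar sets are fine.

## Oblique-lens camera

The virtual camera sits at the scope tip. Its optical axis is the shaft
axis tilted by the lens-offset angle (default 30°, the standard angled
arthroscope) about a fixed perpendicular reference; the cylinder angle θ
rotates the *whole camera basis* about the shaft, so the viewing direction
sweeps a cone of half-angle 30° and the image rotates with the cylinder
(the up-vector is rigidly attached to the lens barrel — the rendered model
must follow the physical rotation of the cylinder). The fixed
perpendicular is chosen deterministically from the shaft axis, making
`C(θ)` a pure function of the geometry and θ.

θ is estimated per frame from the relative transform between the
head marker and the cylinder marker, compared against a reference pair
captured once at θ = 0. The incremental rotation is decomposed as
axis–angle; the signed angle about the shaft axis (range (−180°, 180°]) is
returned together with a misalignment flag raised when the rotation axis
deviates from the shaft by more than 5° — a symptom of a bent mount or a
mis-tracked marker rather than a cylinder spin.

## Camera model and calibration

Projection is pinhole (+z forward, +x right, +y down; 0-based pixel
coordinates, origin top-left, pixel centres at integers) with
Brown–Conrady distortion: radial `(1 + k1 r² + k2 r⁴ + k3 r⁶)` plus the
two tangential terms. The overlay applies distortion *forward* so rendered
geometry matches the distorted video; reverse correction (used when
back-projecting pixels) is the standard fixed-point iteration
`x ← (x_d − tangential(x)) / radial(x)`, tolerance 1e-10 (1e-12 where a
back-projected ray feeds a millimetre-scale measurement), 50 iterations,
with an explicit non-convergence error carrying the final residual. The
default scope camera is 640×480 px, f = 600 px, k1 = −0.25, k2 = 0.05 —
moderate barrel distortion typical of wide-angle endoscope optics; the
distorted radius profile is monotone (hence invertible) over the
calibrated field of view, which `DistortionModel.check_injective`
verifies numerically.

Calibration consumes correspondence sets (planar board corners ↔ observed
pixels); corner detection from images is deliberately out of scope. The
estimator is the classical planar-target method: per-view homographies by
normalized DLT, closed-form intrinsics from the image-of-the-absolute-conic
constraints, per-view extrinsics from the homographies, then joint
trust-region least-squares refinement of intrinsics + 5 distortion
coefficients + per-view poses (scipy `least_squares`, tolerances 1e-12,
at most 200 function evaluations). The synthetic view generator places an
8×6-corner, 4 mm-pitch board ~30 mm from the camera with tilts up to ~35°
— near-fronto-parallel-only views would be degenerate, and a board that
fills the field of view is what conditions the higher radial terms.

## Simulated tracker

Markers are constellations of ≥4 "Xpoint" fiducials (≥1 mm apart,
non-collinear; the default layouts are a square plus one out-of-plane
point, 40–70 mm across with seeded jitter giving each tool a distinct
distance signature). The stereo head is two identical pinhole cameras,
120 mm baseline, converged 10°, f = 1000 px, 1280×960 — a plausible
desk-scale stand-in, all values configurable. An observation transforms
the template by the ground-truth pose, projects into both cameras, adds
i.i.d. Gaussian pixel noise of configurable σ, and triangulates each point
back (midpoint of the shortest segment between the two rays; rays within
0.1° of parallel are refused). Pose estimation is the rigid fit above;
identification returns the registered template with the smallest fit
residual, rejecting matches above a threshold (default 1.0 mm RMS,
configurable — a scaled or deformed constellation cannot be absorbed by a
rigid fit). Correspondence is by index: combinatorial point matching is
tracker firmware and not part of the model. Image-level Xpoint *detection*
is likewise not simulated; σ is a free parameter standing for the
detector's localization noise, with 0.2 px used as the realistic default.
The tracker's intrinsic accuracy is nowhere inferred from published
hardware figures.

Known (and accepted) behaviour: triangulated depth is unbiased only to
first order; at large σ the convexity of depth in the disparity produces a
small systematic bias, which is why the unbiasedness property is asserted
in the small-noise regime.

## Phantom

The generator builds, at true scale, the static scene the physical model
provides: humerus along +z and radius/ulna along +x (a 90°-flexed elbow),
four nerves as 1.5 mm-radius tubes swept along smooth Bézier routes
passing near the joint (parallel-transport frames avoid torsion
artifacts), a stylized skin envelope, a mounting frame block, and the
three marker layouts. Organ meshes are stored organ-locally with a static
placement `T_MO` (model base → organ); the base-plate marker frame *is*
the model base frame. Everything is deterministic under the phantom seed,
which jitters only nerve routes and marker layouts within realistic
bounds. What the phantom does **not** emulate: real segmented-anatomy
surface detail, soft-tissue deformation, marker occlusion, or any
image-formation effects — so passing tests demonstrate correctness of the
geometry/estimation pipeline, not robustness to real-video artifacts.

STL I/O is implemented directly because its contract is load-bearing for
the tests: exact (bitwise) vertex welding with no epsilon merging —
deterministic and reversible — byte-deterministic binary output (fixed
header, attribute byte count 0), ASCII parsed at float32 precision so both
dialects of one mesh weld identically, and truncation/malformed-record
errors that carry byte or line offsets. The installed `trimesh` is used in
tests as an independent reader/writer cross-check only.

## TRE protocol

Defaults follow the bench protocol: working distance 20 mm, circle target
Ø 2 mm, cylinder angles −40°…+40° in 10° steps with endpoints included
(9 angles), checkerboard object (5 mm squares — the pitch only defines the
object plane; errors are measured at the intersection point). The circle
is registered so that a perfect chain projects its centre exactly onto a
checkerboard intersection. One trial: observe all three markers with
noise → estimate poses and θ → run the estimated chain → project the
circle centre (with distortion) → back-project that pixel through the
*true* camera onto the checkerboard plane → report the Euclidean distance
to the true intersection in mm. Measuring on the object plane is the only
hardware-free reading of "position accuracy on the display" and keeps the
unit true; the error readout is a declared definition, not a
reconstruction of any particular bench procedure.

The protocol runs 100 repetitions per angle by default (one-reading-per-
angle "sweep" mode available, matching a single physical sweep);
per-(angle, repetition) RNG streams are derived from (protocol seed, angle
index, repetition index) so results are reproducible under reordering.
Summary statistics use the sample SD (n−1), flagged in the output because
the convention in bench reports is often unstated. The scene places the
phantom 0.5 m from the tracker — the middle of a typical optical tracker's
working range — where 0.2 px of Xpoint noise yields sub-millimetre TRE.
Published hardware numbers for this class of system are noise-regime
dependent and are intentionally not calibration targets; the package
asserts *properties* instead: zero-noise exactness, monotonicity in σ, and
linear scaling of object-plane error with working distance under a pure
pointing (rotation) noise model. The rotation noise model exists precisely
because pixel noise also perturbs translation, which breaks exact
distance proportionality.

## Registration refinement

The bench practice of manually nudging the overlay against visible
anatomy (capitellum, radial head) has no objective function; the
implemented surrogate is a 3D–3D landmark fit: the rigid transform of
model-frame landmarks onto their observed positions becomes a correction
`ΔT` applied in the model frame ahead of the organ placements. A 2D
(ray-based) mode was considered and deferred — the 3D–3D mode is the
testable choice, and is explicitly a stand-in rather than a reconstruction
of the manual procedure.

## Rendering

Overlays are wireframes: each organ's unique mesh edges are near-plane
clipped (0.05 mm), projected with forward distortion, clipped to the image
rectangle (Liang–Barsky, with exact clamping so clipped points honour the
bounds), tagged with the organ name, and composited over the base raster
via Pillow. There is deliberately no hidden-surface removal: the point of
the overlay is to show structures *behind* what the scope sees. Organs
fully behind the camera yield empty primitive lists, not errors; frames
missing a required marker are skipped with a logged reason, never dropped
silently. Rasters are written as binary PGM, which is trivially
byte-deterministic.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use: 1000 random pose sets for
the chain oracle (agreement < 1e-10 mm), 20 random distortion models ×
100×100 grid points for the round trip (< 1e-8), 10 calibration views ×
48 corners, 100 noise-free rigid-fit trials (< 1e-9 mm), 500 seeds per
noise level for the Monte-Carlo orderings, and 56 repetitions × 9 angles
per TRE noise level — sizes chosen so the whole suite gives stable
statistics in tens of seconds on one CPU. Ties in template identification
break lexicographically; degenerate inputs (collinear point sets, empty
meshes, near-parallel rays, non-invertible distortion) raise typed errors
rather than producing numbers.

## Limitations

No image formation (video, lighting, occlusion) is simulated; tracker
noise is a single i.i.d. pixel-noise parameter rather than a measured
hardware model; the elbow is rigid and fixed in flexion, as on the bench —
no articulation or soft-tissue motion; calibration assumes the
Brown–Conrady model rather than a true fisheye (equidistant) projection,
which is an approximation for very wide-angle optics; and absolute TRE
magnitudes depend on the chosen noise regime, so only their structural
properties (exactness, monotonicity, scaling) generalize.
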