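# Methods

## Model

The thoracolumbar spine is modelled as an open chain of 17 rigid
segments (L5, L4, …, L1, T12, …, T1) linked by ideal spherical joints.
The base joint (L5) is fixed at the origin — orientation sensors carry
no position information — so the configuration space is the 17 segment
orientations: 51 rotational degrees of freedom. Each segment's local
frame has +z longitudinal (toward the superior vertebra), +x anterior
and +y to the subject's left; the global frame shares these axes with z
vertical. Orientations are unit quaternions internally; user-facing
angles are intrinsic Z–Y′–X″ yaw–pitch–roll. The sequence is chosen so
that yaw is the rotation about the shared vertical axis, which is what
heading cancellation must remove; pitch is extracted into [−π/2, π/2],
and at gimbal lock (|pitch| within 1e-6 rad of π/2) yaw is set to 0,
roll absorbs the free angle and the triplet is flagged.

Forward kinematics stacks each segment's scaled body height along its
local +z. The skin surface over a vertebra lies posteriorly: the
spinous-process tip at −x by the spinous length, the skin point further
out by the soft-tissue thickness. A natural cubic spline through the 17
skin points, parameterised by cumulative chord length, is the estimated
skin surface; its full arc length is the estimated T1–L5 skin distance.

### Default geometry

| parameter | value | notes |
|---|---|---|
| spinous length anchors | L5 4.5, L1 5.1, T10 4.6, T1 3.1 cm | measured on the multibody model; other 13 levels filled by monotone cubic interpolation over vertebra index |
| soft tissue | 1.35 cm, every level | skin over the spinous tip |
| extra tissue at L5 | 1.7 cm | thicker gluteal/adipose layer of the lower lumbar region |
| body heights | 1.80–2.90 cm table | average adult values shipped in `data/vertebral_geometry.yaml`; absolute values matter little because the chain is rescaled per subject; configurable |
| pelvic anteversion | +10° male, +14° female | added to the L5 pitch; sign configurable |
| tape-measured skin distance | subject input, ~43 ± 4 cm | sets the subject scale |

## Estimation pipeline

One predict → correct → scale pass:

1. Readings are plate-corrected (below), heading-normalised (the base
   sensor's initial yaw is cancelled for the whole set), time-averaged
   per level over the static window (eigenvector quaternion mean), and
   converted to Euler triplets. The anteversion pitch is added at L5.
2. Each angle channel is unwrapped along the chain and interpolated
   over vertebra index (L5=1 … T1=17) with the shape-preserving
   piecewise cubic (Fritsch–Carlson slopes); both endpoints must carry
   sensors — the interpolant is never extrapolated. Forward kinematics
   gives the predicted posture.
3. Per non-base instrumented level, the sagittal angular offset is the
   signed angle, about the sensor's local +y, from the sensor's
   longitudinal axis to the skin-surface segment attached to its
   vertebra (skin point to the superior neighbour's skin point; T1,
   having no superior, uses the segment from T2). Offsets are
   subtracted from the sensor pitches — implemented as pitch
   subtraction in the Euler triplet, i.e. a rotation about the
   intermediate y′ axis, which leaves yaw and roll untouched — and the
   chain is re-interpolated and re-posed.
4. The scale factor is the measured skin distance divided by the
   corrected posture's skin arc length; it rescales all body heights,
   spinous lengths and tissue thicknesses, and the chain is posed a
   final time. Arc-length conservation (final arc = measurement) is
   exact up to quadrature because posed geometry is linear in scale.

**Base-level offset.** The geometric offset correction is deliberately
not applied at L5. Two reasons. Physically, the skin over the sacrum
relates to the L5 body through the pelvic tilt, and that relation is
already corrected by the anteversion constant; applying the segment
correction as well double-counts. Numerically, the L5 skin segment is
dominated by the 1.7 cm soft-tissue step between L5's and L4's skin
points (a ~27° chord tilt over a 2.7 cm body), which makes the
predict→estimate map locally expansive there: its only fixed point is
an unphysiological ~120° offset, and a single subtraction pass
overshoots by tens of degrees. Excluding the base restores a stable,
accurate correction; the remaining levels' offsets are a few degrees
and are recovered essentially exactly in the noiseless closed loop.
This is consistent with the lumbar region being the method's
acknowledged weak spot on real subjects.

**Single pass.** Offsets are estimated once, on the predicted posture.
A `correction_passes` parameter can iterate (estimate on the corrected
posture and subtract again), but iteration is off by default: the
one-pass residual at the corrected levels is second order in the
offset spread, and iterating brings the L5-adjacent instability back
into play.

**Estimated sensor positions** are the skin points of the final
posture at the instrumented levels — sensors physically sit on the
skin. A flag switches to the bare spinous-process tips for comparison
against marker points identified on the processes themselves.

## Sensor processing

*Plate calibration.* Skin IMUs nominally share one Earth frame but
disagree by constant rotations (gravity/North estimation errors). A
static capture with all sensors co-mounted on a rigid plate gives
per-sensor window means (eigenvector average of the accumulated outer
products — immune to quaternion sign flips); the correction
q̄_ref ⊗ q̄ᵢ⁻¹ maps each sensor onto the reference (the L5 sensor, as
model base). A window spread above 2° logs a plate-moved warning. The
reference sensor's correction is the identity by construction, so a
residual common rotation — including the reference's own window noise
— survives calibration; it is exactly what heading normalisation
removes, which is why calibration quality is judged relative to the
reference. With a 0.2°-per-axis, 100-sample window the per-sensor
recovery error is ~0.03–0.05°.

*Marker clusters.* Three markers rigidly fixed to each sensor give its
pose by a least-squares rigid fit of the local template (Kabsch);
residual RMS above 2 mm logs a swap/occlusion warning. With 0.5 mm
marker noise on the ~5 cm housing footprint the attitude precision
bound is ~1.2° (three markers at ~25 mm lever arms); position stays
below 1 mm.

*MARG fusion.* Raw 9-axis streams are fused with the gradient-descent
update: the gyro quaternion derivative minus a β-weighted normalised
gradient of the gravity(+magnetic-field) alignment objective, with the
Earth field re-referenced each step to (b_x, 0, b_z). β defaults to
0.1 s⁻¹ (configurable; there is no published gain for this hardware); a
zero accelerometer norm falls back to gyro-only integration.

## Synthetic data

The generator emulates static standing captures of a cohort (default
14 subjects, 7 per sex, tape distance ~N(43, 4²) cm truncated to
[35, 55]).

*Sagittal profile.* Truth pitch is pinned at six anatomical landmarks —
base inclination at L5; L5 minus the lordosis at L1 (lumbar increments
sum exactly to the stated lordosis); a shallow junction dip (~3°)
bottoming at T10, where normal sagittal alignment is most reclined; an
S-shaped kyphotic rise reaching 33 %/72 % of the total at T7/T4 and
100 % at T1 — and completed through all 17 levels by the same
shape-preserving cubic the estimator uses. This places the truth in
the soft-curvature class the method itself assumes ("spinal curvature
can be approximated by a cubic spline"): the full 6-sensor layout can
represent it exactly, so the noiseless closed loop isolates the
offset/scale machinery, while sparser layouts suffer genuine
interpolation loss. The dip at T10 is deliberately non-monotone
structure: a monotone interpolant cannot reconstruct it inside a gap,
so layouts lacking a T10 sensor degrade — reproducing the
characteristic layout ordering (dropping T10 is the worst 5-sensor
choice; keeping only T4 between the endpoints is the worst 4-sensor
one, since its low-lying reconstruction errors displace every
check-point above). Yaw and roll follow low-amplitude sine profiles
(axial rotation and lateral bend, a few degrees).

*Sensor composition.* A skin sensor reads its vertebra's orientation
with the sagittal skin offset added to pitch. Because the skin-segment
direction itself depends on the neighbouring orientations, the offsets
implied by the geometry are defined self-consistently, as the fixed
point of the predict→estimate map (Newton-solved from the
truth-geometry segment angles; values 2–5°, cached per subject). The
L5 sensor instead under-reads pitch by exactly the anteversion angle
and carries no geometric offset, mirroring the pipeline's base-level
treatment. Heading biases enter as per-sensor Rz rotations applied
identically to standing and plate captures (so calibration can cancel
them); orientation noise is per-sample Gaussian in Euler angles;
marker clusters sit at the truth skin points with the sensor's
orientation plus Gaussian position noise. Everything is seeded and
bit-reproducible; noiseless output is seed-independent.

*What the generator does not emulate* — and what passing tests
therefore do not demonstrate: profiles outside the
six-landmark cubic class (real spines only approximately satisfy the
softness assumption; the residual appears as the few-mm floor real
validations show); soft-tissue motion artifact and posture-dependent
offset drift; magnetometer disturbance fields and gyro bias;
scoliotic/deformed geometries, where the skin-to-bone correspondence
itself changes; measurement error in the tape distance.

## Numerical choices

- Skin spline: natural cubic, chord-length knots; arc length by
  16-point Gauss–Legendre per spline segment (relative error ≪ 1e-6;
  additivity holds to the same order).
- Quaternions canonicalised to w ≥ 0; all averages via the 4 × 4
  outer-product eigenvector.
- Angle channels unwrapped before interpolation to avoid spurious ±2π
  turns at the ±π seam.
- Interpolation abscissa is the integer vertebra index; cumulative
  body height was considered and rejected as the default because it
  makes the interpolant depend on the (subject-scaled) geometry while
  changing results only marginally.
- The generator's fixed-point solve uses scipy's hybrid Newton with
  the truth-geometry chord angles as the start; non-convergence (not
  observed for physiological parameters) raises rather than returning
  an inconsistent subject.
- Degenerate inputs raise typed errors: zero-norm quaternions,
  non-increasing knots, duplicate skin points, missing chain
  endpoints, non-positive scales, collinear marker triangles.

## Limitations

Static standing posture only — no tracking through motion, no
vertebral-load estimation. Accuracy against real anatomy is bounded by
the validation design itself: errors are measured at the sensors
(skin), not at the vertebrae (an X-ray comparison is the missing gold
standard), and the skin-to-bone offsets at and below L1 are the
least-observable part of the chain. The default marker template is a
synthetic stand-in for a housing drawing, not manufacturer data.
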