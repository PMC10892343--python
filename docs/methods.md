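# Methods

This note records the models, conventions, parameter choices and known
limitations behind `frtkit`, at the level of detail a maintainer or a
careful user needs.

## Conventions

Quaternions are scalar-first `(w, x, y, z)`, Hamilton multiplication, and
represent the sensor (body) frame relative to the local ENU Earth frame
(x east, y geomagnetic north, z up): `q ⊗ v ⊗ q*` maps sensor-frame
vectors to Earth, `q* ⊗ v ⊗ q` maps Earth to sensor.  `q` and `−q` are the
same rotation; comparisons use the sign-invariant geodesic angle.

Euler angles are intrinsic Z-Y-X Tait–Bryan (yaw ψ, then pitch θ, then
roll ϕ) with ϕ, ψ ∈ [−180°, 180°] and θ ∈ [−90°, 90°].  The asymmetric
pitch interval forces θ to be the middle rotation, which pins the
decomposition order.  At gimbal lock (θ = ±90°) only the combination of
roll and yaw is observable; the converter reports it entirely as yaw and
sets roll to 0 — a convention, stated here because other packages split it
differently.

## Orientation estimation

The fusion filter integrates the gyroscope quaternion derivative and
applies one normalized gradient-descent step per sample against the
gravity (and optionally Earth-field) alignment objective, scaled by the
gain β.  Design points that are easy to get wrong:

* **Gradient.**  The 3×4 Jacobian is the analytic derivative of the
  rotated reference written in its unit-constrained quadratic form (the
  `1 − 2(y² + z²)`-style matrix entries), with the quaternion treated as a
  free ℝ⁴ vector.  This matches the published scalar-form filter exactly;
  differentiating the raw quaternion sandwich instead adds a radial term
  that changes the step.  A finite-difference check in the test suite
  pins this down.
* **Magnetic reference.**  The measured field is rotated into the Earth
  frame with the previous estimate and its horizontal magnitude collapsed
  onto a single horizontal axis, `b̂ = (0, √(hx²+hy²), 0, hz)`, which
  removes declination and first-order soft-iron effects.  Because that
  axis is Earth *x* while geomagnetic north is ENU *y*, the estimated yaw
  is offset by a constant 90° relative to a true-north reference (such as
  the Android rotation vector).  The benchmark routine removes this offset
  (default 90°, configurable); nothing in the reach computation depends on
  it, since reach extraction is invariant to rotations about z.
* **Gain and convergence.**  The normalized gradient makes the correction
  a constant-rate (~2β rad·s⁻¹) pull, so β is both the drift-rejection
  authority and the convergence speed, and the estimate limit-cycles with
  amplitude ≈ 2βΔt around equilibrium.  Default β = 0.1 at 100 Hz.  Since
  0.1 rad·s⁻¹ cannot close a large initial error quickly, the first
  `init_time_s` = 1 s uses `init_gain` = 2.5 (accelerated initialization,
  standard practice in this filter family); convergence from a 45° error
  then takes well under a second.  β = 0 disables every correction and
  reduces the filter to pure gyro integration, exactly.
* **Motion gating.**  During a reach the accelerometer measures gravity
  plus the motion acceleration; correcting against it tilts the estimate
  so as to absorb precisely the signal the displacement integration
  needs, which collapses the estimated reach.  The correction is therefore
  suspended while the gyro rate magnitude exceeds `motion_gate_rad_s`
  (default 0.05 rad·s⁻¹).  The mask is dilated by ±0.5 s because the lean
  acceleration leads the angular rate at movement onset; the pipeline is
  offline, so acausal dilation is free.  Quiet standing dominates an FRT
  recording, so the filter re-anchors between attempts.
* **Gyro de-biasing.**  The pipeline subtracts the per-axis median of the
  gyroscope track before fusion.  With the correction gated during
  movement, a constant rate bias would otherwise integrate into several
  degrees of tilt over a 4-s reach and leak gravity into the linear
  acceleration; the median over a mostly-quiet recording is a robust
  static bias estimate.  Disable with `debias_gyro=False`.
* The magnetometer is sample-and-held onto the common grid, never
  interpolated; a missing magnetometer simply yields an IMU-only run
  (yaw then unreferenced).

Both gyro-integration forms — the quaternion-derivative form and the 4×4
skew-symmetric rate-matrix form — are implemented and agree to 1e-12 per
step; the additive-identity form `q ← q + ½ Ω q Δt` is used throughout.

## Preprocessing

The nanosecond sensor-event timestamp is authoritative; the millisecond
system timestamp is metadata.  All streams are cubic-spline resampled onto
a uniform 100 Hz grid spanning the accelerometer's record.  Gravity is
removed for movement detection with a zero-phase FIR high-pass (order
1000, cutoff 1 Hz); zero-phase (forward–backward) filtering is used for
every filter in the package so that no group delay leaks into window
placement or distance extraction — an offline-pipeline luxury that also
squares each filter's magnitude response, which is accounted for in the
tests' passband tolerances.

Movement detection is this package's own design (the assessment protocol
fixes only the 5-s analysis window): a moving-RMS envelope (0.5 s) of the
acceleration magnitude, low-pass filtered at 2.5 Hz beforehand because
voluntary reach content lies below ~2 Hz while sensor noise is broadband —
without the band limit the noise floor swallows small reaches.  A burst is
envelope > 4 × median envelope; each burst yields a 5-s window centred on
its envelope centroid; bursts closer than 5 s merge; windows that would
leave the recording are clipped and flagged.  All knobs are arguments.

## Kinematics and reach extraction

Earth-frame linear acceleration is `q ⊗ aˢ ⊗ q* − (0,0,9.81)`.  Each
movement window is integrated independently with zero initial velocity
(the subject stands still between attempts, so rest at the window edge
holds by protocol), using cumulative trapezoids; a zero-phase high-pass
Butterworth (order 5, cutoff 0.01 Hz, second-order-sections form — the
transfer-function form is numerically unusable at 1e-4 of Nyquist) is
applied after each integration stage.

Reach is computed in the XOY plane: direction = first principal axis
(eigen-decomposition of the 2×2 covariance; near-isotropic ties broken by
the larger projected range; orientation fixed to non-negative east
component), distance = max − min of the scalar projections, in cm.
"Extreme points" are read as extremes of the 1-D projection, not the 2-D
diameter pair.  The result is invariant to translations and to rotations
about z by construction.

## Synthetic generator

`simulate_frt_trial` models a hip-hinge: a rigid lever arm of
`sensor_height_m` (default 0.60 m, hip to arm-band) rotates by a
minimum-jerk lean-angle profile from upright to
`arcsin(reach_m / sensor_height_m)` and back over `lean_duration_s`
(default 2 s per half), `n_attempts` times (default 2), separated by quiet
standing (defaults 10 s before the first and between/after attempts; the
total must exceed ~30 s for the order-1000 gravity filter, and the
defaults give 38 s).  Default per-attempt reach is 0.20 m, mid-range for
older adults.  Gyroscope, accelerometer (specific force `Rᵀ(p̈ + g)`) and
magnetometer (Earth field 22 µT north, 40 µT downward — mid-latitude
magnitude and dip) all derive analytically from the one trajectory, so the
emitted truth is exact.  Sampling emulates the target hardware: nominal
400 Hz inertial / 100 Hz magnetic with ±1 ms uniform timestamp jitter.
Noise defaults are smartphone-grade: accelerometer σ = 0.05 m·s⁻², gyro
σ = 0.005 rad·s⁻¹ with a 0.01 rad·s⁻¹ per-axis constant bias,
magnetometer σ = 0.5 µT.  Everything is deterministic under `seed`.

What the generator does **not** model: multi-segment body kinematics (the
arm is rigid with the trunk), soft-iron distortion, accelerometer bias and
scale-factor error, temperature drift, vibration, and magnetic
disturbances from the environment.  Passing tests on this generator
demonstrates the correctness of the algorithmic chain under its stated
assumptions, not field accuracy on human recordings.

## Numerical and degenerate-input choices

* Quaternion normalization rejects near-zero norm (1e-12); rotation inputs
  must be unit to 1e-6.
* A zero-norm accelerometer sample skips the correction for that step
  (gyro-only), flagged in the per-step return.
* A zero gradient (perfect alignment) skips the step rather than dividing
  by zero — this also makes a noise-free aligned static input an exact
  fixed point.
* Reach windows with fewer than two samples, empty trial lists, ages
  outside 20–87, negative distances: explicit `ValueError`s.
* Assessment summaries round half-up in decimal space (clinical-table
  convention); the error column is the absolute difference of the
  *unrounded* means, computed in decimal to avoid binary-float
  representation noise flipping the second decimal.

## Problem sizes and calibrated tolerances

The test suite and the acceptance script use 30-s static runs and 38-s
two-attempt trials at the generator defaults — long enough for the
order-1000 gravity filter and representative of a real assessment, small
enough to keep the full suite under a minute.  The end-to-end displacement
tolerance (4.5 cm absolute error on a noise-free 20 cm trial) was
calibrated once from an oracle sweep of the full chain and frozen in
`tests/fixtures/calibration.json`: the chain systematically overestimates
by ~15–20 % (drift-filter transient plus the β-limit-cycle tilt jitter
leaking a near-constant few-mm·s⁻² into the window), an offset that is
stable across reaches — which is why the estimated-vs-true rank
correlation over the 12–28 cm sweep is exactly 1.

## Known limitations

* Displacement from double-integrated consumer-grade accelerometry remains
  fragile: with the default noise and bias the per-attempt reach error is
  a few centimetres, and orientation error during movement is the dominant
  term.  Zero-velocity updates or smoothing would help and are out of
  scope here.
* Yaw is only as good as the magnetic environment; indoors, steel
  structures can move the reference by tens of degrees.
* The 90° yaw-offset convention (x-axis magnetic reference) must be
  remembered whenever the estimate is compared against a true-north
  reference.
* Band boundaries of the age/sex norm table are integer ages; fractional
  ages are not defined.
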