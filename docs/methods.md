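# Methods

This note documents the models behind `fibrojoint`, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and the
numerical choices that matter.

## Geometry and conventions

Images are `(row, col)`, origin top-left; angles are degrees,
counter-clockwise positive when viewing the sensor (y up).  Quaternions are
`(w, x, y, z)` mapping sensor-frame vectors into the world frame; yaw is the
ZYX-Euler z-rotation.  Physical positions are micrometers relative to the
sensor center; one sensor pixel is `field_mm·1000/sensor_px` µm (25 µm for
the default 2.5-mm field on 100 px).

## Synthetic scenes and captures

The bundle scene is rendered at ≥4× the sensor resolution so sub-pixel rigid
motion is well defined; sensor sampling is an area average over each pixel's
footprint (the identity capture is exactly the block mean of the scene
center).  Scene content: a smooth random fluorescence field (Gaussian-
filtered noise, correlation length ≈4 sensor px, ±25 % contrast), per-patch
transmission gains (±15 %) on the 100 × 100 grid of 6 × 6-fiber
subassemblies, darkened patch-border cladding (periodic at the patch pitch),
a radial vignette, and `n_broken_patches` subassemblies with near-zero gain.
An isotropic optical PSF (Gaussian, σ = 0.6 sensor px by default) is applied
last.  The PSF matters: it bandlimits the scene below the sensor Nyquist so
that bicubic resampling and the sub-pixel closure property (warping a
rotated capture back onto the reference within 1 % of range) are well posed;
without it, the one-pixel patch texture aliases under rotation.

Captures rotate the scene about an axis offset `ecc_um` from the image
center — mechanical eccentricity makes the image center describe a circle,
so the rigid transform from a capture at angle φ to the reference is a
rotation by φ about the center plus a translation of chord length
`2|e|sin(φ/2)`.  An optional angle-dependent sinusoidal rotation offset
models residual transmission error.  Moiré (the fiber lattice beating
against the sensor grid) is a single global 2-D sinusoid, static in sensor
coordinates; its frequency and phase are free parameters because only their
existence, not their values, is characteristic of the device class.
Additive Gaussian noise, clipping and 16-bit quantization close the model.
Not modeled: optical coupling physics (NA, crosstalk), shot-noise statistics,
motion blur.

## Orientation filter

The Madgwick MARG update is implemented in its published gradient-descent
form with one deliberate choice: the state is first propagated by gyro
quaternion integration, and the normalized gradient of the accel + mag
objective is evaluated at the *propagated* state, scaled by `β·dt`.
Evaluating the gradient before propagation (against the newer measurement)
biases the estimate one sample ahead during steady rotation — an error of
`rate·dt` (0.7° at 36 °/s, 50 Hz) independent of β; the predict-then-correct
order removes it.  Stream filtering additionally uses the trapezoidal mean
of consecutive gyro samples, which matters at a 50-Hz rate.

β defaults to 0.1; convergence from a heading error E takes roughly
`E/(2β·rate)` seconds (≈4 s from 45° at 50 Hz), so the stream filter
initializes TRIAD-style from the first accel + mag pair instead of the
identity.  Near-antipodal initial errors (~180°) sit at a saddle of the
objective and converge slowly — inherent to gradient methods.  Hard-iron
calibration is a linear least-squares sphere fit; it requires the sample
cloud to span three dimensions (a yaw-only rotation gives a planar circle
and is rejected).  Soft-iron (ellipsoid) correction and magnetic declination
are out of scope: only relative yaw drives the joint.

## Joint model

Backlash is a pure symmetric dead band of `backlash_usteps`: the output is
dragged so `commanded − output` stays in `[0, backlash]`, i.e. the first
microsteps after a direction reversal produce no output motion.  No
elasticity or torque dynamics; the 1:3 belt enters only as the gear factor
with zero slip.  Anti-backlash locking overshoots OREF by a configurable
offset (default 2× backlash; it must exceed the backlash) and approaches in
a fixed +1 direction, which makes the locked output angle exactly repeatable
— the spread over arbitrary motion histories is 0 µsteps, not merely small.
OREF is therefore defined as this reproducible locked orientation, and HR
characterization references it.  Motion is kinematic with a rate limit
(default 5 rev/s at the shaft); SR "locking" freezes the command during each
exposure window, and the schedule is rejected if exposure + settle leaves no
time to move between frames.  In HYBRID mode, torsion (unwrapped yaw minus
shaft angle) triggers a one-revolution unwind at |torsion| ≥ 360°.

## Registration

`estimate_rigid` is RANSAC (2-point minimal samples, 1-px inlier tolerance,
1000 iterations, seeded) over matched keypoints, refitted with the
closed-form 2-D Procrustes solution on the consensus set; scale and shear
are excluded by construction.  Keypoints come from scikit-image's SIFT with
Lowe's ratio test; any rotation-invariant detector satisfying the property
tests would do.  Keypoint localization scatters ~0.5 px on this texture, so
a full-frame estimate carries ~0.1–0.2° of rotation noise; where µm-level
accuracy is needed (LUT calibration, characterization measurements) the
feature-based estimate is polished by `refine_rigid`, a Gauss-Newton
minimization of the intensity SSD with a finite-difference Jacobian over
`(θ, t_r, t_c)`.  Its residual support is fixed at the initial estimate and
excludes pixels whose source leaves the frame (eroded by 4 px), plus
anything outside a caller-supplied validity mask — zero-filled out-of-field
regions would otherwise bias the fit.  On noiseless captures the refined
estimate is accurate to ~0.001° and ~0.02 px.

The LUT stores, per calibrated motor angle, the total transform to the OREF
reference, re-expressed about the sensor center with the rotation lifted
near the motor angle so interpolation is smooth; queries interpolate
linearly and periodically in angle, and an identity entry at OREF is always
included.  Application is a single inverse-mapped bicubic resampling with a
validity mask.  The eccentricity vector is recovered from the translation
circle by least squares on `t(φ) = (I − R(φ))e`.

### Characterization protocol

`simulate_characterization` reproduces the three image-series conditions
with 25 images each: **NM** (no motion — the measurement noise floor),
**HR** (random wander + anti-backlash re-lock before each capture), **SR**
(captures at angles spanning 9–345°, registered through a LUT calibrated in
the same run at 30° spacing).  Because the dead-band model repositions
*exactly*, HR would be statistically identical to NM; a small residual
repositioning jitter (0.004° and 0.8 µm sd — the scale of bearing runout and
belt non-repeatability in a device of this class) models the mechanical
imperfection that separates HR from the noise floor in practice.  The study
conditions for the acceptance characterization are 100 µm of eccentricity,
a 0.05° residual rotation sinusoid, 80 counts of sensor noise and a
120-count static moiré.  Under SR, the moiré is rotated along with the
content while the reference's moiré stays put, and the LUT's linear
interpolation of the eccentric translation circle leaves mid-segment errors
of a few µm — together these reproduce the qualitative structure of the
hardware measurements: median translation error NM ≤ HR ≤ SR, and the
fraction of pixels within ±0.25 % of full range NM ≥ HR ≥ SR.  Rotation
medians for NM and HR are statistically tied, as in the hardware data.
Absolute hardware numbers are properties of a physical device and are not
targets of the simulation.

## VSD chain

ΔF/F₀ uses the mean of the three frames around the reference index;
non-positive baselines are flagged invalid, not infinite.  Note that ΔF/F is
normalized to the acquisition-start baseline while the generator's wave
amplitude is a fraction of shutter-open fluorescence; comparisons convert by
the bleach level at the reference window (`1 + bleach(t_ref)`).

The bleach fit low-passes the ROI-mean trace with a 4th-order Butterworth at
2.5 Hz, applied forward–backward for zero phase.  On a 1-s trace the filter's
transient spans a large fraction of the data, so the trace is first
detrended with a preliminary quadratic, only the residual is filtered
(maximal odd-extension padding), and the trend is added back — polynomials
pass through exactly, and a noiseless quadratic is recovered to machine
precision.  The quadratic is fitted on the absolute time axis (offset by the
pre-exposure), so the leading coefficient `a` is comparable across trials;
`ln(a)` regressed on pre-exposure time (degree-2 polynomial, covariance-based
confidence band) captures how pre-exposure flattens the decay.  Correction
subtracts the fitted scalar trace from every pixel, in the units of the
input sequence.

Patterned-noise removal nulls listed frequency bins (cycles/px) and their
conjugates in the 2-D FFT of every frame; DC is rejected, outputs are real,
unmasked bins are untouched, and the energy removed equals the masked-bin
energy exactly (Parseval).  Spatial smoothing convolves with a normalized
truncated Gaussian (5 × 5 default, σ = kernel/5, reflective boundaries).

## Behavior metrics

Cumulated revolutions are `(yaw − yaw₀)/360` on unwrapped yaw.  D9/Q2 are
time-weighted quantiles of |revolutions| — magnitude, so both torsion
directions count equally — computed exactly for the piecewise-linear trace
by inverting the time-below-level function (bisection); the histogram uses
0.25-revolution bins.  Rate metrics average over consecutive retained sample
pairs, excluding pairs spanning a confidence-filtering gap (default
threshold 1.5× the median interval); mean displacement is reported in mm/s.
Paired comparisons use the two-sided Wilcoxon signed-rank or paired t-test;
all-zero differences are reported as degenerate (p = 1), and an exact
zero-variance shift as p = 0.

## Synthetic study conditions and their limits

Trajectories are correlated random walks: an Ornstein–Uhlenbeck turn rate
(stationary sd 45 °/s, correlation time 0.5 s — giving sampling-rate-
independent angular-velocity statistics) around a constant turning bias,
constant speed 50 mm/s, softly steered from the 150-mm arena wall.  The
active-vs-inactive joint contrast is emulated by a ±36 °/s turning bias;
only the *direction* of the D9/velocity/displacement contrast carries over
to animal data — magnitudes, pauses, thigmotaxis and gait are not modeled.
The IMU model is a level head (yaw-only motion, gravity on z); pitch/roll
excursions during rearing are not simulated, so filter accuracy on real
head motion will be somewhat worse than the noiseless-stream bounds.

Problem sizes used throughout (25 images per characterization series, 512
VSD frames, 20-replicate behavior contrasts, 100-lock repeatability runs)
match the device's acquisition granularity while keeping any analysis
re-runnable in minutes on one CPU.
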