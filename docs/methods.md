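# Methods

## Problem and model

`chaintrack` tracks a kinematic chain instrumented with one IMU per rigid
segment. No IMU-to-segment (I2S) calibration is assumed: the chain is
modeled purely as global IMU poses plus IMU-local joint positions, and the
joint positions are estimated online together with the poses. The
estimated state per time step is

* per IMU *i*: body-frame angular velocity `w_i` (rad/s), navigation-frame
  linear acceleration `a_i` (m/s²) — the process-noise-driven block `X1` —
  and orientation (as Modified Rodrigues Parameters `chi_i` of `R^{N I_i}`),
  position `p_i` and velocity `v_i` — part of the noise-free block `X2`;
* per joint *(i, j)*: the joint position expressed in both adjacent IMU
  frames, `J_{ij}^{I_i}` and `J_{ij}^{I_j}` (constants);
* per anchored IMU *l*: the local offset `J_fix^{I_l}` of a known
  navigation-frame fixed point.

The navigation frame has its z-axis up (gravity `g = (0, 0, -9.81)` m/s²)
and x-axis toward magnetic north. Quaternions are Hamilton, scalar-first;
MRPs use the shadow set for `|chi| > 1`.

### Motion model

Constant acceleration and constant angular rate over one sampling
interval `dt`:

    p <- p + dt v + dt²/2 a          v <- v + dt a          a <- a + dt w_a
    q <- q (.) exp(dt/2 w)           w <- w + dt w_w

with white process noises `w_a ~ N(0, Q_a)`, `w_w ~ N(0, Q_w)` entering
scaled by `dt`, so the discrete process covariance carries `dt² Q_a` /
`dt² Q_w` on the acceleration and rate blocks and is **exactly zero** on
every `X2` row and column. This split is what keeps the parameter
estimates consistent: `X2` follows the motion model strictly and receives
information only through measurements.

### Measurement models

Per step the estimator stacks

* accelerometer `y_a = R^T (a - g) + e`, gyroscope `y_w = w + e`
  (always);
* a heading-only magnetometer constraint
  `0 = atan2((R y_m)_y, (R y_m)_x) + e` — only the heading is used, the
  dip angle carries no information, which limits the influence of
  magnetic disturbances (optional; rows with a near-vertical projected
  field are skipped);
* joint-position and joint-velocity constraints equating the joint point
  and its velocity seen from both adjacent IMUs (the chain "glue");
* a fixed-point constraint `0 = P_fix - p_l - R_l J_fix + e`;
* a zero-velocity constraint `0 = v_c + e` when the SHOE detector flags
  IMU *c*.

An acceleration-level joint constraint (equating joint-point
accelerations, with the angular acceleration from a backward difference
quotient on the rate states and unit measurement covariance) is provided
solely as an ablation; used alone it lacks the position/velocity drift
correction through the chain and does not converge (demonstrated in the
acceptance suite).

### Estimator

Prediction: `x <- F(x)`, `P <- Q + F' P F'^T` (the Jacobian `F'` has exact
integrator rows and finite-difference orientation rows). Update: the
posterior mean minimizes the Mahalanobis measurement residual plus the
Mahalanobis deviation from the prediction, solved by Gauss-Newton with
Armijo backtracking (max 10 iterations, step tolerance 1e-8, `c = 1e-4`,
at most 20 halvings). The covariance uses the Kalman form
`(I - K H) P` with `H` at the predicted mean (a flag switches to the
converged mean). On a linear model one Gauss-Newton iteration equals the
Kalman update exactly, so the estimator contains the EKF as a special
case; this is asserted to machine precision in the tests.

Jacobians are numerical on every orientation-dependent block (central
differences over the three MRP components, step `1e-6 max(1, |x|)`) and
analytic only where the model is exactly linear (identity, `±I`, `±R`,
`dt I` blocks). A dense full-state finite-difference oracle in the test
suite checks the assembled Jacobians at 1e-5 relative.

Initialization assumes a stationary chain: kinematic states start at
zero mean under broad priors; orientations come from the
accelerometer/magnetometer triad (the only point where magnetometer data
is mandatory); joint and fixed offsets are drawn from `N(0, l² I)` with
`l = 0.4` m (the maximal segment length) to support Monte Carlo restarts.

The convergence indicator for a joint is `s_c sqrt(lambda_max)` of the
averaged two 3×3 joint-offset marginals, with
`s_c = sqrt(chi2_quantile(0.99, 3)) ≈ 3.37` — an approximate 99%
credibility radius in meters. The source prints the scaled eigenvalue
without the square root; we take the root so the indicator has length
units and matches the chi-square motivation.

### Default covariances

Defaults: `Q_a = 3e5 I`,
`Q_w = 1e4 I`, `Sigma_a = 1e-2 I`, `Sigma_w = 1e-3 I`, `Sigma_mag = 1e-2 I`
(its (1,1) entry is used for the scalar heading row), `Sigma_cp = 1e-4 I`,
`Sigma_cv = 1e-3 I`, `Sigma_fix = 1e-4 I`, `Sigma_zvd = 1e-4 I`, priors
`1·I` on velocity/acceleration/rate/position, `1e-6 I` on the MRP,
`0.16 I` on joint offsets.

### SHOE zero-velocity detector

`T = mean_k(|y_a,k - g û|²/s_a² + |y_w,k|²/s_w²)` over a sliding window
(`û` the direction of the window-mean accelerometer sample). Defaults:
window `b = 11` samples, threshold `gamma = 50`, `s_a²`/`s_w²` equal to
the accelerometer/gyroscope measurement variances. The threshold sits
between the statistic's stance expectation (~6 at the simulator's noise
levels) and swing values (>10³), chosen a priori; all four are
configurable. Among multiple candidates below the threshold only the
lowest-statistic IMU is kept, and at most one zero-velocity row enters
the update.

## Synthetic data

### Three-link chain

An arm-like chain of three segments (lengths 0.35, 0.35, 0.30 m; the
joint prior scale `l = 0.4` is an upper bound on these) anchored at the
origin. Segment frames have their origin at the proximal joint and the
distal joint at `(L, 0, 0)`; IMUs sit on the segments through fixed
homogeneous I2S transforms (rotation + offsets of 5–20 cm). Every joint
degree of freedom follows a sinusoidal rotation-vector profile
`theta(t) = e(t) · A sin(2 pi f t + phi)`:

* amplitudes 0.17–1.1 rad and frequencies k/6.29 s (k = 1, 2, 3, i.e.
  0.16–0.48 Hz), three distinct harmonics per joint with varied phases,
  periodic with the 629-sample cycle at 100 Hz;
* `e(t)` is a C² ramp over the first second so the chain starts exactly
  at rest, matching the estimator's stationary initialization assumption.

The table is chosen so peak angular rates (~1–1.6 rad/s) excite every
joint degree of freedom while peak angular accelerations stay near
2 rad/s². The latter matters: the estimator's zero-order-hold transition
accrues a per-step orientation error proportional to angular
acceleration, and because the orientation block carries no process noise
the filter corrects it only at the (small) gain implied by the default
covariances. The resulting equilibrium bias is ~0.2–0.4° of orientation
and a few millimeters of joint position at 2 rad/s², and grows roughly
linearly with angular acceleration. Faster, more ballistic profiles
converge sooner (more excitation) but carry proportionally larger
steady-state biases; the default sits in the regime where sub-degree
orientation accuracy and millimeter-level segment lengths are reachable
at these covariance settings.

Ground-truth velocities, accelerations and body rates come from
4th-order central differences (5-point stencil, h = 1 ms) of the
closed-form pose trajectory; truth is kinematically consistent with the
measurement models to below 1e-8 (the two C²-only ramp junctions carry a
~1e-3 m/s² one-sided-stencil error in the stored acceleration). IMU data
inverts the measurement models with white Gaussian noise; default
standard deviations 0.1 m/s² (accel), 0.0316 rad/s (gyro) and 0.01 a.u.
(mag) match the default measurement covariances, so the filter is
well-specified. The navigation magnetic field is `(cos 60°, 0, -sin 60°)`
(unit horizontal component, arbitrary dip).

What the generator does *not* emulate: sensor biases and scale factors,
soft-tissue artifact, magnetic disturbances, sampling jitter, and any
mismatch between the filter's noise model and the data. Passing tests
therefore demonstrate correctness and consistency of the estimator under
its own model class plus a continuous-time motion it can only
approximate — not robustness to real-sensor pathologies.

### Gait-like chain

A pelvis plus two foot IMUs translating forward. Feet alternate exact
zero-velocity dwells (0.72 s each at the default 1.2 s cycle) and
C²-smooth swings (quintic smoothstep advance, `sin⁴` lift, a smooth
swing-phase pitch rotation so the gyro channel separates swing from
stance). This generator exists to exercise the SHOE detector and
zero-velocity updates with known dwell timing; unlike the three-link
chain it does not enforce constant joint offsets, so it is not a
full-filter consistency fixture.

## Numerical choices and degenerate inputs

* Covariances are symmetrized after every prediction and update; an
  eigenvalue below `-1e-9 · trace` raises instead of being clipped.
* The magnetometer row set is decided once per update (at the predicted
  mean) so the Gauss-Newton objective keeps a fixed row structure;
  near-vertical projected fields (< 1e-3 of the field norm horizontal)
  drop the row.
* Heading residuals and their finite differences are wrapped to
  (-pi, pi] to avoid branch-cut artifacts.
* The triad rejects accelerometer/magnetometer pairs within 5° of
  (anti-)parallel and warns when the accelerometer norm is outside
  [0.5 g, 1.5 g].
* MRP shadow-set switching is applied after every propagation and update;
  the covariance is left in the pre-switch chart (switches occur only at
  180° rotations, which the simulated motions do not reach).
* Streams must be constant-rate: gaps above twice the sampling interval
  or rate jitter above 1% are rejected up front.

## Known limitations

* The global-MRP parameterization makes the estimator only approximately
  equivariant under rigid heading rotations of the scene (the prior and
  the linearization live in chart coordinates); the residual effect is at
  the 0.01° level in the tests. An error-state formulation would be
  exactly equivariant but is a different algorithm.
* Without the magnetometer model the global heading is unobservable and
  performs a slow random walk driven by gyro noise; relative orientations
  remain accurate.
* Joint positions on (near-)hinge joints are identifiable only up to the
  hinge axis; nothing in the estimator regularizes this case.
* Sensor biases are not estimated; a pre-processing utility subtracts
  per-axis means over a user-marked static interval.
* Stationary phases shrink the joint-offset covariance without adding
  information in new directions, which can make estimates transiently
  overconfident when excitation resumes — visible as excursions of the
  joint-position error after early convergence in the simulation study.
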