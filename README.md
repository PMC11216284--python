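# chaintrack

Self-calibrating inertial motion capture for kinematic chains: a
recursive Bayesian estimator that tracks the global poses of a network of
body-worn IMUs and simultaneously estimates the sensor-local positions of
the joints connecting them — with **no IMU-to-segment calibration**.

Inertial human motion capture normally requires registering every sensor
to the anatomy of the segment it sits on; that calibration is the main
obstacle to reliable in-field use. `chaintrack` removes it for joint
tracking: the chain is modeled as IMU poses `(R^{N I_i}, I_i^N)` plus
IMU-local joint offsets `J_{ij}^{I_i}`, `J_{ij}^{I_j}`, and everything is
estimated online from raw accelerometer/gyroscope data (plus one
magnetometer sample per sensor for initialization). Segment lengths fall
out of the converged joint offsets.

## The estimator

The state is split as `X = (X¹, X²)`: angular velocities and linear
accelerations (`X¹`) carry process noise because the IMU data addresses
them directly; orientations, positions, velocities and all joint/fixed
offsets (`X²`) follow the motion model exactly. Each step performs

* **prediction** — constant-acceleration / constant-rate transition with
  covariance `P = Q + F P Fᵀ`, where `Q` is zero on every `X²` block;
* **update** — Gauss–Newton (with line search) minimization of
  `‖y − H(X)‖²_{Σ⁻¹} + ‖X − X̂‖²_{P⁻¹}`, i.e. an iterated-EKF step that
  reduces exactly to the Kalman update for linear models. Measurement
  models: accelerometer, gyroscope, heading-only magnetometer, joint
  position/velocity constraints, fixed-point anchor and SHOE
  zero-velocity updates.

A per-joint convergence indicator `s_c √λ_max` of the joint-offset
covariance (with `s_c = √χ²₀.₉₉(3) ≈ 3.37`) reports an approximate 99%
credibility radius in meters.

Full model equations, defaults, and numerical choices: `docs/methods.md`.

## Worked example

Simulate two motion cycles of a noisy three-link chain fixed in space,
track it from a random joint initialization, and evaluate:

```bash
chaintrack simulate --out-stream stream.h5 --out-truth truth.h5 --seed 0
chaintrack track    --stream stream.h5 --out result.h5 --seed 0
chaintrack evaluate --result result.h5 --truth truth.h5 --out-dir eval/
chaintrack report   --result result.h5 --truth truth.h5 --out-dir eval/
```

`evaluate` prints a JSON summary like:

```json
{
  "n_steps": 1256,
  "final_segment_lengths_m": {"0": 0.35032, "1": 0.35508},
  "final_joint_uncertainty_m": {"0-1": 0.01213, "1-2": 0.00801},
  "final_joint_endpoint_errors_m": [0.00942, 0.00493, 0.00465, 0.00343],
  "final_segment_length_errors_m": {"0": 0.00032, "1": 0.00508},
  "relative_angle_rmse_deg": {"0-1": 1.018, "1-2": 0.636},
  "convergence_sample_2cm": 326
}
```

Reading: the two computable segment lengths (true values 0.35 m) are
recovered to a few millimeters after 1256 samples (12.6 s at 100 Hz),
starting from joint offsets drawn with a 0.4 m prior scale; the
convergence indicator has shrunk to the centimeter level; relative IMU
orientation RMSE is around a degree (the average includes the
initialization transient); all four joint-offset estimates stay within
2 cm of truth from sample 326 onward. `report` renders the corresponding
convergence and uncertainty plots as PNGs.

The same estimator runs on real recordings via
`chaintrack track --stream your_data.csv --config chain.yaml`; the
expected stream schema and an adapter mapping for external HDF5 exports
are documented in `src/chaintrack/dataset_schema.yaml`.

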