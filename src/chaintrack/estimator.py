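"""Recursive Bayesian estimator for IMU kinematic chains.

Each time step performs

1. *prediction* — the split-state transition: mean through the motion
   model, covariance ``P = Q + F P F^T`` where ``Q`` has non-zero entries
   only on the angular-velocity and acceleration blocks;
2. *measurement update* — Gauss-Newton minimization (with Armijo
   backtracking line search) of the sum of the Mahalanobis measurement
   residual and the Mahalanobis deviation from the prediction; the
   covariance follows the Kalman form ``(I - K H) P`` with the measurement
   Jacobian evaluated at the predicted mean.

With a linear measurement model a single Gauss-Newton iteration reproduces
the Kalman filter update exactly, so the estimator reduces to the EKF as a
special case (asserted in the tests).

The joint-position convergence indicator is the scaled largest eigenvalue
of the averaged per-joint offset covariance, ``s_c * sqrt(lambda_max)``
with ``s_c = sqrt(chi2_quantile(0.99, 3)) ~ 3.37``, an approximate 99%
credibility radius in meters.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.stats import chi2

from .chain_model import (
    ChainTopology,
    EstimatorConfig,
    StateEstimate,
    StateLayout,
    build_layout,
)
from .chain_model import EstimationError
from .measurement_models import MeasurementFrame, assemble, shoe_detect
from .motion_model import motion_jacobian, process_covariance, propagate
from .rotations import matrix_to_quat, mrp_shadow, quat_to_mrp, triad_orientation

__all__ = [
    "initialize",
    "predict",
    "update",
    "gauss_newton_update",
    "joint_uncertainty",
    "fixed_point_uncertainty",
    "run",
    "subtract_static_bias",
    "TrackingResult",
    "UpdateDiagnostics",
    "EstimationError",
]

_SC_99 = float(np.sqrt(chi2.ppf(0.99, df=3)))


# ---------------------------------------------------------------------------
# initialization

def initialize(
    topology: ChainTopology,
    frame: MeasurementFrame,
    config: EstimatorConfig,
    rng: np.random.Generator | int | None = None,
    overrides: dict | None = None,
) -> StateEstimate:
    """Initial state from one stationary frame.

    Velocities, accelerations, angular rates and positions start at zero
    mean under their priors; orientations come from the accelerometer/
    magnetometer triad (the one point where magnetometer data is
    mandatory); joint and fixed-point offsets are drawn from their prior
    so Monte Carlo restarts explore the initialization uncertainty.

    ``overrides`` maps layout keys (e.g. ``("pos", 0)``) to mean values and
    is applied after construction (used for correct-initialization and
    gauge experiments).
    """
    if frame.mag is None:
        raise ValueError(
            "initialization requires a magnetometer sample for every IMU "
            "(triad attitude determination)"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    layout = build_layout(topology)
    mean = np.zeros(layout.dim)
    cov = np.zeros((layout.dim, layout.dim))

    for i in range(topology.n_imus):
        R = triad_orientation(frame.acc[i], frame.mag[i], gravity=config.gravity)
        layout.set(mean, ("mrp", i), quat_to_mrp(matrix_to_quat(R)))
    Lj = np.linalg.cholesky(config.sigma_init_joint)
    for k in range(len(topology.joints)):
        layout.set(mean, ("joint_i", k), Lj @ rng.standard_normal(3))
        layout.set(mean, ("joint_j", k), Lj @ rng.standard_normal(3))
    for l in topology.fixed_imus:
        layout.set(mean, ("fix", l), Lj @ rng.standard_normal(3))

    priors = {
        "omega": config.sigma_init_omega,
        "acc": config.sigma_init_acc,
        "mrp": config.sigma_init_mrp,
        "pos": config.sigma_init_pos,
        "vel": config.sigma_init_vel,
        "joint_i": config.sigma_init_joint,
        "joint_j": config.sigma_init_joint,
        "fix": config.sigma_init_joint,
    }
    for key, s in layout.blocks.items():
        cov[s, s] = priors[key[0]]

    if overrides:
        for key, value in overrides.items():
            layout.set(mean, key, np.asarray(value, dtype=float))

    est = StateEstimate(mean=mean, cov=cov, layout=layout, t=frame.t)
    est.validate()
    return est


# ---------------------------------------------------------------------------
# prediction

def predict(est: StateEstimate, config: EstimatorConfig, dt: float | None = None) -> StateEstimate:
    """Time update: propagate mean and covariance one sampling interval."""
    if dt is None:
        dt = config.dt
    layout = est.layout
    mean = propagate(est.mean, layout, dt)
    F = motion_jacobian(est.mean, layout, dt, config.fd_step)
    cov = process_covariance(layout, config, dt) + F @ est.cov @ F.T
    cov = 0.5 * (cov + cov.T)
    out = StateEstimate(mean=mean, cov=cov, layout=layout, t=est.t + dt)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Gauss-Newton measurement update

@dataclass
class UpdateDiagnostics:
    iterations: int = 0
    objective: list = field(default_factory=list)
    step_norms: list = field(default_factory=list)
    converged: bool = True


def gauss_newton_update(
    x0: np.ndarray,
    P: np.ndarray,
    fun,
    max_iter: int = 10,
    step_tol: float = 1e-8,
    armijo_c: float = 1e-4,
    max_halvings: int = 20,
):
    """Minimize ``r(x)^T S^-1 r(x) + (x - x0)^T P^-1 (x - x0)``.

    ``fun(x, with_jacobian)`` must return ``(r, Jr, Sigma)`` where ``Jr``
    is ``dr/dx`` (may be None when ``with_jacobian`` is False).  Returns
    ``(x, diagnostics)``.  With a linear residual the first iteration is
    the exact (Kalman) posterior mean.
    """
    P = 0.5 * (P + P.T)
    try:
        P_chol = scipy.linalg.cho_factor(P)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise EstimationError("prediction covariance not positive definite") from exc

    def p_inv_apply(v):
        return scipy.linalg.cho_solve(P_chol, v)

    P_inv = scipy.linalg.cho_solve(P_chol, np.eye(P.shape[0]))

    diag = UpdateDiagnostics()
    x = x0.copy()
    r, Jr, sigma = fun(x, True)
    sigma_chol = scipy.linalg.cho_factor(sigma)

    def objective(x, r):
        dx = x - x0
        return float(r @ scipy.linalg.cho_solve(sigma_chol, r) + dx @ p_inv_apply(dx))

    obj = objective(x, r)
    diag.objective.append(obj)

    for it in range(max_iter):
        Sr = scipy.linalg.cho_solve(sigma_chol, r)
        SJ = scipy.linalg.cho_solve(sigma_chol, Jr)
        dx = x - x0
        grad = 2.0 * (Jr.T @ Sr + p_inv_apply(dx))
        A = Jr.T @ SJ + P_inv
        A = 0.5 * (A + A.T)
        try:
            delta = np.linalg.solve(A, -(Jr.T @ Sr + p_inv_apply(dx)))
        except np.linalg.LinAlgError as exc:
            raise EstimationError("singular Gauss-Newton normal equations") from exc
        step_norm = float(np.linalg.norm(delta))
        diag.step_norms.append(step_norm)
        if step_norm < step_tol:
            break
        # Armijo backtracking on the full objective
        slope = float(grad @ delta)
        alpha = 1.0
        accepted = False
        for _ in range(max_halvings + 1):
            x_try = x + alpha * delta
            r_try = fun(x_try, False)[0]
            obj_try = objective(x_try, r_try)
            if obj_try <= obj + armijo_c * alpha * slope:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            diag.converged = False
            break
        x = x_try
        r = r_try
        obj = obj_try
        diag.objective.append(obj)
        diag.iterations = it + 1
        if it + 1 < max_iter:
            _, Jr, _ = fun(x, True)
    return x, diag


def update(
    est_pred: StateEstimate,
    frame: MeasurementFrame,
    config: EstimatorConfig,
    topology: ChainTopology | None = None,
    prev_omega: np.ndarray | None = None,
) -> tuple[StateEstimate, UpdateDiagnostics]:
    """Measurement update at the predicted estimate.

    Returns the posterior estimate and solver diagnostics.  The covariance
    uses the measurement Jacobian evaluated at the *predicted* mean (set
    ``config.h_at_converged_mean`` to evaluate it at the converged mean
    instead).
    """
    layout = est_pred.layout
    topology = topology or layout.topology

    # decide magnetometer-row skips once, at the predicted mean
    mag_skip: set[int] = set()
    if config.use_magnetometer and frame.mag is not None:
        from .rotations import mrp_to_matrix

        for i in range(layout.n_imus):
            R = mrp_to_matrix(layout.get(est_pred.mean, ("mrp", i)))
            m_nav = R @ frame.mag[i]
            if np.hypot(m_nav[0], m_nav[1]) < 1e-3 * np.linalg.norm(frame.mag[i]):
                mag_skip.add(i)
        if mag_skip:
            warnings.warn(
                f"magnetometer heading rows skipped for IMUs {sorted(mag_skip)}: "
                "projected field nearly vertical",
                stacklevel=2,
            )

    def fun(x, with_jacobian):
        obs = assemble(
            x,
            layout,
            frame,
            config,
            topology,
            with_jacobian=with_jacobian,
            prev_omega=prev_omega,
            mag_skip=mag_skip,
        )
        return obs.r, obs.jac, obs.sigma

    x, diag = gauss_newton_update(
        est_pred.mean,
        est_pred.cov,
        fun,
        max_iter=config.gn_max_iter,
        step_tol=config.gn_step_tol,
        armijo_c=config.armijo_c,
        max_halvings=config.armijo_max_halvings,
    )

    # covariance via the Kalman form with H at the predicted (or converged) mean
    lin_point = x if config.h_at_converged_mean else est_pred.mean
    obs = assemble(
        lin_point,
        layout,
        frame,
        config,
        topology,
        with_jacobian=True,
        prev_omega=prev_omega,
        mag_skip=mag_skip,
    )
    Jr = obs.jac
    P = est_pred.cov
    S = Jr @ P @ Jr.T + obs.sigma
    try:
        S_chol = scipy.linalg.cho_factor(0.5 * (S + S.T))
    except np.linalg.LinAlgError as exc:
        raise EstimationError("singular innovation covariance") from exc
    PJt = P @ Jr.T
    cov = P - PJt @ scipy.linalg.cho_solve(S_chol, PJt.T)
    cov = 0.5 * (cov + cov.T)

    # keep the MRP blocks on the principal branch
    for i in range(layout.n_imus):
        layout.set(x, ("mrp", i), mrp_shadow(layout.get(x, ("mrp", i))))

    out = StateEstimate(mean=x, cov=cov, layout=layout, t=frame.t)
    out.validate()
    return out, diag


# ---------------------------------------------------------------------------
# convergence indicator

def joint_uncertainty(est: StateEstimate, joint_index: int) -> float:
    """99% credibility radius (m) of a joint position estimate.

    Averages the two 3x3 marginal covariances of the joint offset (one per
    adjacent IMU frame) and returns ``s_c * sqrt(lambda_max)``.
    """
    avg = 0.5 * (est.marginal(("joint_i", joint_index)) + est.marginal(("joint_j", joint_index)))
    lam = float(np.linalg.eigvalsh(0.5 * (avg + avg.T))[-1])
    return _SC_99 * float(np.sqrt(max(lam, 0.0)))


def fixed_point_uncertainty(est: StateEstimate, l: int) -> float:
    """Convergence indicator of a fixed-point offset estimate."""
    m = est.marginal(("fix", l))
    lam = float(np.linalg.eigvalsh(0.5 * (m + m.T))[-1])
    return _SC_99 * float(np.sqrt(max(lam, 0.0)))


# ---------------------------------------------------------------------------
# pre-processing

def subtract_static_bias(
    frames: list[MeasurementFrame],
    static_slice: slice,
    expected_acc: np.ndarray | None = None,
) -> list[MeasurementFrame]:
    """Subtract per-axis gyro (and optional accel) means over a static interval.

    ``expected_acc`` is the per-IMU (N, 3) specific force a perfectly
    calibrated stationary sensor would measure; when given, the mean
    deviation from it is removed from the accelerometer stream as well.
    """
    gyro_bias = np.mean([f.gyro for f in frames[static_slice]], axis=0)
    acc_bias = 0.0
    if expected_acc is not None:
        acc_bias = np.mean([f.acc for f in frames[static_slice]], axis=0) - expected_acc
    return [
        MeasurementFrame(t=f.t, acc=f.acc - acc_bias, gyro=f.gyro - gyro_bias, mag=f.mag, zupt=f.zupt)
        for f in frames
    ]


# ---------------------------------------------------------------------------
# tracking loop

@dataclass
class TrackingResult:
    """Per-step state trajectory and diagnostics of one tracking run."""

    layout: StateLayout
    topology: ChainTopology
    times: np.ndarray  # (T,)
    means: np.ndarray  # (T, dim)
    joint_uncertainty: np.ndarray  # (T, n_joints)
    fixed_uncertainty: np.ndarray  # (T, n_fixed)
    zupt_flags: np.ndarray  # (T, N) bool
    gn_iterations: np.ndarray  # (T,)
    objective: np.ndarray  # (T,) final Gauss-Newton objective per step
    final: StateEstimate
    cov_snapshots: list = field(default_factory=list)  # (step, cov) pairs

    @property
    def n_steps(self) -> int:
        return self.times.shape[0]

    def block_series(self, key: tuple) -> np.ndarray:
        """(T, 3) trajectory of one state block."""
        return self.means[:, self.layout[key]]

    def rotations(self, i: int) -> np.ndarray:
        """(T, 3, 3) estimated orientation series R^{NI_i}."""
        from .rotations import mrp_to_matrix

        chis = self.block_series(("mrp", i))
        return np.stack([mrp_to_matrix(chi) for chi in chis])


def run(
    frames,
    topology: ChainTopology,
    config: EstimatorConfig,
    rng: np.random.Generator | int | None = None,
    overrides: dict | None = None,
    record_cov_every: int = 0,
) -> TrackingResult:
    """Track a constant-rate stream of measurement frames.

    The first frame initializes the state (triad orientations, random
    joint offsets); every further frame is processed as SHOE detection
    (when enabled), prediction, and Gauss-Newton measurement update.
    Magnetometer rows are used after initialization only when
    ``config.use_magnetometer`` is set.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least two frames to track")
    dts = np.diff([f.t for f in frames])
    if np.any(dts > 2.0 * config.dt + 1e-12):
        raise EstimationError("stream gap exceeds 2 sampling intervals")
    if np.any(dts <= 0):
        raise EstimationError("non-monotonic time stamps")

    est = initialize(topology, frames[0], config, rng=rng, overrides=overrides)
    layout = est.layout
    n_j = len(topology.joints)
    n_f = len(topology.fixed_imus)
    T = len(frames)
    means = np.empty((T, layout.dim))
    junc = np.zeros((T, n_j))
    func_ = np.zeros((T, n_f))
    zupt_flags = np.zeros((T, topology.n_imus), dtype=bool)
    gn_iters = np.zeros(T, dtype=int)
    objective = np.zeros(T)
    times = np.array([f.t for f in frames])
    cov_snapshots = []

    def record(k, est):
        means[k] = est.mean
        for kj in range(n_j):
            junc[k, kj] = joint_uncertainty(est, kj)
        for kf, l in enumerate(topology.fixed_imus):
            func_[k, kf] = fixed_point_uncertainty(est, l)
        if record_cov_every and k % record_cov_every == 0:
            cov_snapshots.append((k, est.cov.copy()))

    record(0, est)

    use_shoe = config.use_zupt and len(topology.zupt_candidates) > 0
    buffers = {
        c: (deque(maxlen=config.shoe_window), deque(maxlen=config.shoe_window))
        for c in topology.zupt_candidates
    }
    if use_shoe:
        for c in topology.zupt_candidates:
            buffers[c][0].append(frames[0].acc[c])
            buffers[c][1].append(frames[0].gyro[c])

    prev_omega = np.stack([layout.get(est.mean, ("omega", i)) for i in range(topology.n_imus)])
    for k in range(1, T):
        frame = frames[k]
        if use_shoe:
            windows = {}
            for c in topology.zupt_candidates:
                buffers[c][0].append(frame.acc[c])
                buffers[c][1].append(frame.gyro[c])
                windows[c] = (np.asarray(buffers[c][0]), np.asarray(buffers[c][1]))
            selected, _ = shoe_detect(windows, config)
            flags = np.zeros(topology.n_imus, dtype=bool)
            if selected is not None:
                flags[selected] = True
            frame = MeasurementFrame(
                t=frame.t, acc=frame.acc, gyro=frame.gyro, mag=frame.mag, zupt=flags
            )
            zupt_flags[k] = flags
        est = predict(est, config, dt=float(times[k] - times[k - 1]))
        est, diag = update(est, frame, config, topology, prev_omega=prev_omega)
        gn_iters[k] = diag.iterations
        objective[k] = diag.objective[-1]
        prev_omega = np.stack(
            [layout.get(est.mean, ("omega", i)) for i in range(topology.n_imus)]
        )
        record(k, est)

    return TrackingResult(
        layout=layout,
        topology=topology,
        times=times,
        means=means,
        joint_uncertainty=junc,
        fixed_uncertainty=func_,
        zupt_flags=zupt_flags,
        gn_iterations=gn_iters,
        objective=objective,
        final=est,
        cov_snapshots=cov_snapshots,
    )
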