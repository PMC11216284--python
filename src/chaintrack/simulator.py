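"""Synthetic kinematic-chain trajectories and noisy IMU data.

Two generators are provided:

* :func:`three_link_truth` — an arm-like three-link chain whose proximal
  segment rotates about a point fixed in space; every joint degree of
  freedom is driven by a sinusoidal angle profile, which provides the
  motion excitation the joint-position estimation needs.  The IMUs sit on
  the segments through fixed IMU-to-segment transforms.
* :func:`gait_like_truth` — a forward-translating pelvis with two foot
  IMUs that alternate exact zero-velocity dwell phases and C2-smooth swing
  phases (with swing-phase foot pitch), for exercising the zero-velocity
  detector.

Ground-truth velocities, accelerations and body angular rates are obtained
by 4th-order central differencing of the closed-form pose trajectory on a
5-point stencil, which keeps the truth kinematically consistent with the
measurement models to well below 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain_model import ChainTopology, StateLayout
from .measurement_models import MeasurementFrame
from .rotations import matrix_to_quat, quat_conjugate, quat_exp, quat_log, quat_multiply, quat_to_matrix, quat_to_mrp

__all__ = [
    "SimConfig",
    "GaitSimConfig",
    "GroundTruth",
    "three_link_truth",
    "gait_like_truth",
    "synthesize_imu",
    "EQ_I2S_TRANSFORMS",
]


def _default_i2s() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IMU-to-segment homogeneous transforms of the simulated three-link chain."""
    t0 = np.array(
        [
            [0.0, 0.0, 1.0, 0.1],
            [0.0, 1.0, 0.0, 0.0],
            [-1.0, 0.0, 0.0, 0.15],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    t1 = np.array(
        [
            [0.0, -1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.1],
            [-1.0, 0.0, 0.0, 0.2],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    t2 = np.array(
        [
            [0.0, -1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.1],
            [-1.0, 0.0, 0.0, 0.05],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return (t0, t1, t2)


EQ_I2S_TRANSFORMS = _default_i2s()

# fixed sinusoid table: per joint (base anchor, joint 0-1, joint 1-2) and
# per rotation-vector component: amplitude [rad], cycle harmonic k
# (frequency = k / cycle period, 0.16-0.48 Hz) and phase.  Amplitudes are
# large and frequencies low: peak angular rates ~1-1.6 rad/s excite every
# joint DoF while peak angular accelerations stay ~2 rad/s^2, so the
# constant-rate motion model remains a good description of one 10 ms step
# (arm-like motion rather than ballistic motion).  Each joint mixes three
# distinct harmonics so the excitation directions keep changing.
_AMPLITUDES = np.array([[1.1, 0.55, 0.17], [0.55, 0.17, 1.1], [0.17, 1.1, 0.55]])
_HARMONICS = np.array([[1, 2, 3], [2, 3, 1], [3, 1, 2]], dtype=float)
_PHASES = (
    np.pi
    / 3.0
    * np.array([[0.0, 2.0, 4.0], [1.0, 3.0, 5.0], [2.0, 4.0, 0.5]], dtype=float)
)


@dataclass
class SimConfig:
    """Three-link chain simulation settings."""

    segment_lengths: tuple[float, ...] = (0.35, 0.35, 0.30)
    i2s: tuple[np.ndarray, ...] = field(default_factory=_default_i2s)
    amplitudes: np.ndarray = field(default_factory=lambda: _AMPLITUDES.copy())
    harmonics: np.ndarray = field(default_factory=lambda: _HARMONICS.copy())
    phases: np.ndarray = field(default_factory=lambda: _PHASES.copy())
    cycle_samples: int = 629
    startup_ramp: float = 1.0  # seconds; C2 ramp-in so the chain starts at rest
    rate: float = 100.0
    n_samples: int = 1256
    accel_noise_std: float = 0.1
    gyro_noise_std: float = 0.0316
    mag_noise_std: float = 0.01
    mag_field: tuple[float, float, float] = (np.cos(np.pi / 3), 0.0, -np.sin(np.pi / 3))
    gravity: float = 9.81
    fixed_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    heading_offset: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.harmonics = np.asarray(self.harmonics, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        if any(L <= 0 for L in self.segment_lengths):
            raise ValueError("segment lengths must be positive")
        if np.any(self.harmonics <= 0):
            raise ValueError("harmonics (hence frequencies) must be positive")
        for T in self.i2s:
            R = np.asarray(T)[:3, :3]
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or not np.isclose(
                np.linalg.det(R), 1.0, atol=1e-9
            ):
                raise ValueError("I2S rotation block must be a proper rotation")

    @property
    def cycle_period(self) -> float:
        return self.cycle_samples / self.rate


@dataclass
class GaitSimConfig:
    """Gait-like chain (pelvis + two feet) for zero-velocity testing."""

    step_length: float = 0.5
    cycle_time: float = 1.2
    swing_fraction: float = 0.4  # dwell lasts (1 - swing_fraction) * cycle_time
    lift_height: float = 0.05
    pitch_amplitude: float = 0.5
    pelvis_height: float = 1.0
    foot_spacing: float = 0.2
    rate: float = 100.0
    n_samples: int = 1200
    accel_noise_std: float = 0.1
    gyro_noise_std: float = 0.0316
    mag_noise_std: float = 0.01
    mag_field: tuple[float, float, float] = (np.cos(np.pi / 3), 0.0, -np.sin(np.pi / 3))
    gravity: float = 9.81
    seed: int = 0


@dataclass
class GroundTruth:
    """True poses, kinematics and joint geometry of a simulated chain."""

    t: np.ndarray  # (T,)
    rot: np.ndarray  # (T, N, 3, 3) R^{NI}
    pos: np.ndarray  # (T, N, 3)
    vel: np.ndarray  # (T, N, 3)
    acc: np.ndarray  # (T, N, 3)
    omega: np.ndarray  # (T, N, 3) body-frame angular velocity
    topology: ChainTopology
    joint_local_i: np.ndarray  # (J, 3) constant J_{i,j}^{I_i}
    joint_local_j: np.ndarray  # (J, 3) constant J_{i,j}^{I_j}
    fix_local: dict  # imu index -> (3,) constant J_fix^{I_l}
    joint_nav: np.ndarray  # (T, J, 3) true joint points in navigation frame
    segment_lengths: np.ndarray  # per segment, meters
    rate: float
    gravity: float = 9.81
    mag_field: np.ndarray = field(default_factory=lambda: np.array([np.cos(np.pi / 3), 0.0, -np.sin(np.pi / 3)]))

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    @property
    def n_imus(self) -> int:
        return self.rot.shape[1]

    def state_mean(self, k: int, layout: StateLayout) -> np.ndarray:
        """Pack the true state at step ``k`` into a layout-ordered mean vector."""
        mean = np.zeros(layout.dim)
        for i in range(self.n_imus):
            layout.set(mean, ("omega", i), self.omega[k, i])
            layout.set(mean, ("acc", i), self.acc[k, i])
            layout.set(mean, ("mrp", i), quat_to_mrp(matrix_to_quat(self.rot[k, i])))
            layout.set(mean, ("pos", i), self.pos[k, i])
            layout.set(mean, ("vel", i), self.vel[k, i])
        for kk in range(len(self.topology.joints)):
            layout.set(mean, ("joint_i", kk), self.joint_local_i[kk])
            layout.set(mean, ("joint_j", kk), self.joint_local_j[kk])
        for l in self.topology.fixed_imus:
            layout.set(mean, ("fix", l), self.fix_local[l])
        return mean


# ---------------------------------------------------------------------------
# pose sampling with 4th-order stencil kinematics

_STENCIL_H = 1e-3
_D1 = np.array([1.0, -8.0, 0.0, 8.0, -1.0]) / 12.0  # x f(t + m h), m = -2..2
_D2 = np.array([-1.0, 16.0, -30.0, 16.0, -1.0]) / 12.0


def _kinematics_from_poses(pose_fn, times: np.ndarray, n_imus: int):
    """Sample poses and derive velocity/acceleration/angular rate.

    ``pose_fn(t)`` returns ``(R, p)`` arrays of shape (N, 3, 3) and (N, 3).
    """
    T = times.shape[0]
    h = _STENCIL_H
    rot = np.empty((T, n_imus, 3, 3))
    pos = np.empty((T, n_imus, 3))
    vel = np.empty((T, n_imus, 3))
    acc = np.empty((T, n_imus, 3))
    omg = np.empty((T, n_imus, 3))
    for kt, t in enumerate(times):
        samples = [pose_fn(t + m * h) for m in (-2, -1, 0, 1, 2)]
        R0, p0 = samples[2]
        rot[kt] = R0
        pos[kt] = p0
        ps = np.stack([s[1] for s in samples])  # (5, N, 3)
        vel[kt] = np.tensordot(_D1, ps, axes=1) / h
        acc[kt] = np.tensordot(_D2, ps, axes=1) / (h * h)
        for i in range(n_imus):
            q0 = matrix_to_quat(R0[i])
            q0c = quat_conjugate(q0)
            phis = []
            for m, s in zip((-2, -1, 0, 1, 2), samples):
                if m == 0:
                    phis.append(np.zeros(3))
                else:
                    phis.append(2.0 * quat_log(quat_multiply(q0c, matrix_to_quat(s[0][i]))))
            omg[kt, i] = np.tensordot(_D1, np.stack(phis), axes=1) / h
    return rot, pos, vel, acc, omg


def _rotvec_matrix(v: np.ndarray) -> np.ndarray:
    return quat_to_matrix(quat_exp(0.5 * v))


def _three_link_pose_fn(config: SimConfig):
    lengths = np.asarray(config.segment_lengths, dtype=float)
    i2s = [np.asarray(T, dtype=float) for T in config.i2s]
    fixed = np.asarray(config.fixed_point, dtype=float)
    freqs = config.harmonics / config.cycle_period
    psi = config.heading_offset
    Rz = np.array(
        [
            [np.cos(psi), -np.sin(psi), 0.0],
            [np.sin(psi), np.cos(psi), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )

    ramp = config.startup_ramp

    def angles(t):
        th = config.amplitudes * np.sin(2 * np.pi * freqs * t + config.phases)
        if ramp > 0.0:
            # C2 smooth start from rest: angle, rate and acceleration all
            # vanish at t = 0 (the initialization assumes a stationary chain)
            th = th * _smoothstep5(t / ramp)
        return th

    def pose(t):
        th = angles(t)
        R_imu = np.empty((3, 3, 3))
        p_imu = np.empty((3, 3))
        R_seg = Rz
        origin = fixed
        for s in range(3):
            R_seg = R_seg @ _rotvec_matrix(th[s])
            R_si = i2s[s][:3, :3]
            t_si = i2s[s][:3, 3]
            R_imu[s] = R_seg @ R_si
            p_imu[s] = origin + R_seg @ t_si
            origin = origin + R_seg @ np.array([lengths[s], 0.0, 0.0])
        return R_imu, p_imu

    def joints_nav(t):
        th = angles(t)
        R_seg = Rz
        origin = fixed
        pts = []
        for s in range(3):
            R_seg = R_seg @ _rotvec_matrix(th[s])
            origin = origin + R_seg @ np.array([lengths[s], 0.0, 0.0])
            if s < 2:
                pts.append(origin.copy())
        return np.stack(pts)

    return pose, joints_nav


def three_link_topology() -> ChainTopology:
    return ChainTopology(
        imu_ids=("imu0", "imu1", "imu2"),
        joints=((0, 1), (1, 2)),
        fixed_imus=(0,),
        fixed_point_nav=((0.0, 0.0, 0.0),),
    )


def three_link_truth(config: SimConfig | None = None) -> GroundTruth:
    """Ground-truth trajectory of the fixed-base three-link chain."""
    config = config or SimConfig()
    pose_fn, joints_fn = _three_link_pose_fn(config)
    times = np.arange(config.n_samples) / config.rate
    rot, pos, vel, acc, omg = _kinematics_from_poses(pose_fn, times, 3)

    lengths = np.asarray(config.segment_lengths, dtype=float)
    jl_i = np.empty((2, 3))
    jl_j = np.empty((2, 3))
    for k in range(2):
        # joint (k, k+1): at (L_k, 0, 0) in segment k, at origin of segment k+1
        Ti, Tj = np.asarray(config.i2s[k]), np.asarray(config.i2s[k + 1])
        jl_i[k] = Ti[:3, :3].T @ (np.array([lengths[k], 0.0, 0.0]) - Ti[:3, 3])
        jl_j[k] = Tj[:3, :3].T @ (-Tj[:3, 3])
    T0 = np.asarray(config.i2s[0])
    fix_local = {0: T0[:3, :3].T @ (-T0[:3, 3])}

    topo = three_link_topology()
    psi = config.heading_offset
    Rz = np.array(
        [[np.cos(psi), -np.sin(psi), 0.0], [np.sin(psi), np.cos(psi), 0.0], [0.0, 0.0, 1.0]]
    )
    fixed_nav = Rz @ np.asarray(config.fixed_point, dtype=float)
    topo = ChainTopology(
        imu_ids=topo.imu_ids,
        joints=topo.joints,
        fixed_imus=topo.fixed_imus,
        fixed_point_nav=(tuple(fixed_nav),),
    )
    joint_nav = np.stack([joints_fn(t) for t in times])
    return GroundTruth(
        t=times,
        rot=rot,
        pos=pos,
        vel=vel,
        acc=acc,
        omega=omg,
        topology=topo,
        joint_local_i=jl_i,
        joint_local_j=jl_j,
        fix_local=fix_local,
        joint_nav=joint_nav,
        segment_lengths=lengths,
        rate=config.rate,
        gravity=config.gravity,
        mag_field=np.asarray(config.mag_field, dtype=float),
    )


# ---------------------------------------------------------------------------
# gait-like chain

def _smoothstep5(u: np.ndarray | float):
    """C2 smoothstep (zero velocity and acceleration at both ends)."""
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u * u)


def _foot_trajectory(t: float, cfg: GaitSimConfig, phase_offset: float):
    """(x, z, pitch) of one foot; exact dwell between swings."""
    tc = cfg.cycle_time
    u_total = t / tc + phase_offset
    n = np.floor(u_total)
    u = u_total - n
    sw = cfg.swing_fraction
    if u < sw:
        s = u / sw
        x = cfg.step_length * (n + _smoothstep5(s))
        z = cfg.lift_height * np.sin(np.pi * s) ** 4
        pitch = cfg.pitch_amplitude * np.sin(2 * np.pi * s) * np.sin(np.pi * s) ** 2
    else:
        x = cfg.step_length * (n + 1.0)
        z = 0.0
        pitch = 0.0
    return x, z, pitch


def gait_like_topology() -> ChainTopology:
    return ChainTopology(
        imu_ids=("pelvis", "left_foot", "right_foot"),
        joints=((0, 1), (0, 2)),
        zupt_candidates=(1, 2),
    )


def gait_like_truth(config: GaitSimConfig | None = None) -> GroundTruth:
    """Forward-translating pelvis + two feet with exact zero-velocity dwells.

    Intended for exercising the SHOE detector and zero-velocity updates;
    unlike the three-link chain, the constant-joint-offset consistency of
    the full chain is not enforced.
    """
    cfg = config or GaitSimConfig()

    def pose(t):
        R = np.empty((3, 3, 3))
        p = np.empty((3, 3))
        xl, zl, pl = _foot_trajectory(t, cfg, 0.0)
        xr, zr, pr = _foot_trajectory(t, cfg, 0.5)
        p[1] = (xl, cfg.foot_spacing, zl)
        p[2] = (xr, -cfg.foot_spacing, zr)
        R[1] = _rotvec_matrix(np.array([0.0, pl, 0.0]))
        R[2] = _rotvec_matrix(np.array([0.0, pr, 0.0]))
        p[0] = (0.5 * (xl + xr), 0.0, cfg.pelvis_height)
        R[0] = np.eye(3)
        return R, p

    times = np.arange(cfg.n_samples) / cfg.rate
    rot, pos, vel, acc, omg = _kinematics_from_poses(pose, times, 3)
    topo = gait_like_topology()
    nj = len(topo.joints)
    return GroundTruth(
        t=times,
        rot=rot,
        pos=pos,
        vel=vel,
        acc=acc,
        omega=omg,
        topology=topo,
        joint_local_i=np.zeros((nj, 3)),
        joint_local_j=np.zeros((nj, 3)),
        fix_local={},
        joint_nav=np.zeros((cfg.n_samples, nj, 3)),
        segment_lengths=np.array([]),
        rate=cfg.rate,
        gravity=cfg.gravity,
        mag_field=np.asarray(cfg.mag_field, dtype=float),
    )


# ---------------------------------------------------------------------------
# IMU synthesis

def synthesize_imu(
    truth: GroundTruth,
    accel_noise_std: float = 0.1,
    gyro_noise_std: float = 0.0316,
    mag_noise_std: float = 0.01,
    rng: np.random.Generator | int | None = None,
    with_mag: bool = True,
) -> list[MeasurementFrame]:
    """Generate noisy IMU streams from a ground-truth trajectory.

    Inverts the measurement models: ``y_a = R^T (Idd - g) + noise``,
    ``y_w = omega + noise``, ``y_m = R^T m^N + noise``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    g = np.array([0.0, 0.0, -truth.gravity])
    frames: list[MeasurementFrame] = []
    T, N = truth.n_samples, truth.n_imus
    acc_noise = accel_noise_std * rng.standard_normal((T, N, 3))
    gyro_noise = gyro_noise_std * rng.standard_normal((T, N, 3))
    mag_noise = mag_noise_std * rng.standard_normal((T, N, 3))
    for k in range(T):
        acc = np.empty((N, 3))
        mag = np.empty((N, 3)) if with_mag else None
        for i in range(N):
            Rt = truth.rot[k, i].T
            acc[i] = Rt @ (truth.acc[k, i] - g) + acc_noise[k, i]
            if with_mag:
                mag[i] = Rt @ truth.mag_field + mag_noise[k, i]
        frames.append(
            MeasurementFrame(
                t=float(truth.t[k]),
                acc=acc,
                gyro=truth.omega[k] + gyro_noise[k],
                mag=mag,
            )
        )
    return frames
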