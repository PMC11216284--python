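"""Measurement models: residuals, Jacobians, noise stacking, SHOE detector.

All models are written as residual functions ``r(X)``; the estimator treats
``r`` as the innovation of an (implicit or explicit) measurement and uses
``H = -dr/dX`` in the covariance update, so the sign convention of any
individual residual is immaterial as long as residual and Jacobian agree.

Models
------
* accelerometer:    ``r = y_a - R^T (Idd - g)``            (always active)
* gyroscope:        ``r = y_w - omega``                    (always active)
* magnetometer:     heading-only scalar ``r = -atan2((R y_m)_y, (R y_m)_x)``
* joint position:   equates the joint point seen from both adjacent IMUs
* joint velocity:   time derivative of the joint-position constraint
* joint acceleration (ablation): equates joint-point accelerations, with
  angular acceleration from a difference quotient on the angular-velocity
  states; unit measurement covariance
* fixed position:   one IMU moves around a known navigation-frame point
* zero velocity:    ``r = -Id_c`` when the SHOE detector fires for IMU c

Jacobians: blocks in which a model is exactly linear are filled
analytically; every block involving the orientation MRP is filled by
central finite differences on the three MRP components (the package's
numerical-derivative policy, verified against a dense FD oracle in the
tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain_model import ChainTopology, EstimatorConfig, StateLayout
from .rotations import mrp_to_matrix, skew

__all__ = [
    "MeasurementFrame",
    "StackedObservation",
    "accel_residual",
    "gyro_residual",
    "mag_heading_residual",
    "joint_position_residual",
    "joint_velocity_residual",
    "accel_level_joint_residual",
    "fixed_position_residual",
    "zero_velocity_residual",
    "assemble",
    "shoe_statistic",
    "shoe_detect",
]


@dataclass
class MeasurementFrame:
    """One synchronized multi-IMU sample.

    ``acc``/``gyro`` are ``(N, 3)`` arrays (m/s^2, rad/s); ``mag`` is an
    optional ``(N, 3)`` array in arbitrary units; ``zupt`` is an optional
    boolean array flagging at most one zero-velocity IMU.
    """

    t: float
    acc: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray | None = None
    zupt: np.ndarray | None = None

    def __post_init__(self):
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        if self.mag is not None:
            self.mag = np.atleast_2d(np.asarray(self.mag, dtype=float))
        if self.acc.shape != self.gyro.shape or self.acc.shape[1] != 3:
            raise ValueError("acc and gyro must both be (N, 3)")
        if not (np.all(np.isfinite(self.acc)) and np.all(np.isfinite(self.gyro))):
            raise ValueError("non-finite IMU sample")
        if self.zupt is not None:
            self.zupt = np.asarray(self.zupt, dtype=bool)
            if self.zupt.sum() > 1:
                raise ValueError("at most one zero-velocity flag may be active")


@dataclass
class StackedObservation:
    """Stacked residual vector, residual Jacobian and block-diagonal noise."""

    r: np.ndarray
    jac: np.ndarray | None  # dr/dX, rows x state dim
    sigma: np.ndarray  # rows x rows, block diagonal
    labels: list[tuple]  # (kind, identifier) per row block

    @property
    def rows(self) -> int:
        return self.r.shape[0]


# ---------------------------------------------------------------------------
# individual residuals (reference implementations, also used by assemble)

def _gravity(config_or_g) -> np.ndarray:
    g = config_or_g.gravity if hasattr(config_or_g, "gravity") else float(config_or_g)
    return np.array([0.0, 0.0, -g])


def accel_residual(mean, layout: StateLayout, i: int, y_a, gravity: float = 9.81) -> np.ndarray:
    """Specific-force residual ``y_a - R^T (Idd - g)`` for IMU ``i``."""
    R = mrp_to_matrix(layout.get(mean, ("mrp", i)))
    acc = layout.get(mean, ("acc", i))
    return np.asarray(y_a, dtype=float) - R.T @ (acc - np.array([0.0, 0.0, -gravity]))


def gyro_residual(mean, layout: StateLayout, i: int, y_w) -> np.ndarray:
    return np.asarray(y_w, dtype=float) - layout.get(mean, ("omega", i))


def mag_heading_residual(
    mean, layout: StateLayout, i: int, y_m, min_horizontal: float = 1e-3
) -> float:
    """Heading-only magnetometer residual (scalar, wrapped to (-pi, pi]).

    The field rotated into the navigation frame should point toward
    magnetic north (zero y-component); only the heading angle is
    constrained, the dip angle carries no information.

    Raises
    ------
    ValueError
        If the projected horizontal field is shorter than
        ``min_horizontal`` times the total field norm (vertical field; the
        heading is undefined and the row must be skipped).
    """
    y_m = np.asarray(y_m, dtype=float)
    R = mrp_to_matrix(layout.get(mean, ("mrp", i)))
    m_nav = R @ y_m
    horiz = np.hypot(m_nav[0], m_nav[1])
    if horiz < min_horizontal * np.linalg.norm(y_m):
        raise ValueError("projected magnetic field nearly vertical; heading undefined")
    r = -np.arctan2(m_nav[1], m_nav[0])
    return float((r + np.pi) % (2 * np.pi) - np.pi)


def joint_position_residual(mean, layout: StateLayout, k: int) -> np.ndarray:
    """Joint connection at position level for joint index ``k``.

    The joint point expressed through IMU i must coincide with the joint
    point expressed through IMU j (navigation frame).
    """
    i, j = layout.topology.joints[k]
    Ri = mrp_to_matrix(layout.get(mean, ("mrp", i)))
    Rj = mrp_to_matrix(layout.get(mean, ("mrp", j)))
    pi = layout.get(mean, ("pos", i))
    pj = layout.get(mean, ("pos", j))
    Jani = layout.get(mean, ("joint_i", k))
    Janj = layout.get(mean, ("joint_j", k))
    return -(pi + Ri @ Jani - pj - Rj @ Janj)


def joint_velocity_residual(mean, layout: StateLayout, k: int) -> np.ndarray:
    """Joint connection at velocity level (time derivative of the position one)."""
    i, j = layout.topology.joints[k]
    Ri = mrp_to_matrix(layout.get(mean, ("mrp", i)))
    Rj = mrp_to_matrix(layout.get(mean, ("mrp", j)))
    vi = layout.get(mean, ("vel", i))
    vj = layout.get(mean, ("vel", j))
    wi = layout.get(mean, ("omega", i))
    wj = layout.get(mean, ("omega", j))
    Jani = layout.get(mean, ("joint_i", k))
    Janj = layout.get(mean, ("joint_j", k))
    return -(vi + Ri @ np.cross(wi, Jani) - vj - Rj @ np.cross(wj, Janj))


def accel_level_joint_residual(
    mean, layout: StateLayout, k: int, prev_omega: np.ndarray, dt: float
) -> np.ndarray:
    """Acceleration-level joint connection (ablation model).

    Equates the two joint-point accelerations
    ``Idd + R ([w x][w x] + [wd x]) J`` across the pair; the angular
    acceleration ``wd`` is a backward difference quotient of the
    angular-velocity states (``prev_omega`` is the (N, 3) array of the
    previous step's estimates).
    """
    i, j = layout.topology.joints[k]

    def side(idx, Jkey):
        R = mrp_to_matrix(layout.get(mean, ("mrp", idx)))
        a = layout.get(mean, ("acc", idx))
        w = layout.get(mean, ("omega", idx))
        wd = (w - prev_omega[idx]) / dt
        J = layout.get(mean, Jkey)
        return a + R @ (np.cross(w, np.cross(w, J)) + np.cross(wd, J))

    return -(side(i, ("joint_i", k)) - side(j, ("joint_j", k)))


def fixed_position_residual(mean, layout: StateLayout, l: int) -> np.ndarray:
    """Fixed-point residual: IMU ``l`` moves around a known anchor point."""
    R = mrp_to_matrix(layout.get(mean, ("mrp", l)))
    p = layout.get(mean, ("pos", l))
    Jfix = layout.get(mean, ("fix", l))
    return layout.topology.fixed_point(l) - p - R @ Jfix


def zero_velocity_residual(mean, layout: StateLayout, c: int) -> np.ndarray:
    return -layout.get(mean, ("vel", c))


# ---------------------------------------------------------------------------
# stacking

class _OrientationContext:
    """Per-IMU rotation matrices plus MRP-perturbed variants for FD columns."""

    def __init__(self, mean, layout: StateLayout, fd_step: float, with_jacobian: bool):
        self.layout = layout
        self.R = []
        self.pert = []  # [(h_k, R_plus_k, R_minus_k) for k in 0..2] per IMU
        for i in range(layout.n_imus):
            chi = layout.get(mean, ("mrp", i))
            self.R.append(mrp_to_matrix(chi))
            if with_jacobian:
                rows = []
                for k in range(3):
                    h = fd_step * max(1.0, abs(chi[k]))
                    cp, cm = chi.copy(), chi.copy()
                    cp[k] += h
                    cm[k] -= h
                    rows.append((h, mrp_to_matrix(cp), mrp_to_matrix(cm)))
                self.pert.append(rows)

    def d_Rv_dchi(self, i: int, v: np.ndarray) -> np.ndarray:
        """3x3 matrix: column k = d(R_i v)/d chi_k by central differences."""
        out = np.empty((3, 3))
        for k, (h, Rp, Rm) in enumerate(self.pert[i]):
            out[:, k] = (Rp @ v - Rm @ v) / (2.0 * h)
        return out

    def d_Rtv_dchi(self, i: int, v: np.ndarray) -> np.ndarray:
        """Column k = d(R_i^T v)/d chi_k."""
        out = np.empty((3, 3))
        for k, (h, Rp, Rm) in enumerate(self.pert[i]):
            out[:, k] = (Rp.T @ v - Rm.T @ v) / (2.0 * h)
        return out


def assemble(
    mean: np.ndarray,
    layout: StateLayout,
    frame: MeasurementFrame,
    config: EstimatorConfig,
    topology: ChainTopology | None = None,
    with_jacobian: bool = True,
    prev_omega: np.ndarray | None = None,
    mag_skip: frozenset | set = frozenset(),
) -> StackedObservation:
    """Stack residuals, Jacobian and noise for all enabled models.

    Accelerometer and gyroscope rows are always present; magnetometer,
    joint-position/velocity, acceleration-level joint (ablation), fixed
    point and zero-velocity rows follow the configuration toggles and the
    frame's flags.  ``mag_skip`` lists IMU indices whose magnetometer rows
    are dropped (near-vertical projected field), decided once per update so
    the Gauss-Newton objective keeps a fixed row set.
    """
    topology = topology or layout.topology
    ctx = _OrientationContext(mean, layout, config.fd_step, with_jacobian)
    g = np.array([0.0, 0.0, -config.gravity])

    rows: list[np.ndarray] = []
    jacs: list[list[tuple[slice, np.ndarray]]] = []  # sparse (col-slice, block) rows
    sigmas: list[np.ndarray] = []
    labels: list[tuple] = []
    I3 = np.eye(3)

    def add(kind, ident, r, blocks, sigma):
        rows.append(np.atleast_1d(r))
        jacs.append(blocks)
        sigmas.append(np.atleast_2d(sigma))
        labels.append((kind, ident))

    for i in range(layout.n_imus):
        acc = layout.get(mean, ("acc", i))
        v = acc - g
        r = frame.acc[i] - ctx.R[i].T @ v
        blocks = []
        if with_jacobian:
            blocks = [
                (layout[("acc", i)], -ctx.R[i].T),
                (layout[("mrp", i)], -ctx.d_Rtv_dchi(i, v)),
            ]
        add("accel", i, r, blocks, config.sigma_acc)

        r = frame.gyro[i] - layout.get(mean, ("omega", i))
        blocks = [(layout[("omega", i)], -I3)] if with_jacobian else []
        add("gyro", i, r, blocks, config.sigma_gyro)

        if config.use_magnetometer and frame.mag is not None and i not in mag_skip:
            y_m = frame.mag[i]
            m_nav = ctx.R[i] @ y_m
            r = -np.arctan2(m_nav[1], m_nav[0])
            r = (r + np.pi) % (2 * np.pi) - np.pi
            blocks = []
            if with_jacobian:
                row = np.empty((1, 3))
                for k, (h, Rp, Rm) in enumerate(ctx.pert[i]):
                    mp, mm = Rp @ y_m, Rm @ y_m
                    ap = -np.arctan2(mp[1], mp[0])
                    am = -np.arctan2(mm[1], mm[0])
                    d = ap - am
                    d = (d + np.pi) % (2 * np.pi) - np.pi  # guard the branch cut
                    row[0, k] = d / (2.0 * h)
                blocks = [(layout[("mrp", i)], row)]
            add("mag", i, r, blocks, config.sigma_mag[:1, :1])

    for k, (i, j) in enumerate(topology.joints):
        Jani = layout.get(mean, ("joint_i", k))
        Janj = layout.get(mean, ("joint_j", k))
        if config.use_joint_position_model:
            r = -(
                layout.get(mean, ("pos", i)) + ctx.R[i] @ Jani
                - layout.get(mean, ("pos", j)) - ctx.R[j] @ Janj
            )
            blocks = []
            if with_jacobian:
                blocks = [
                    (layout[("pos", i)], -I3),
                    (layout[("pos", j)], I3),
                    (layout[("joint_i", k)], -ctx.R[i]),
                    (layout[("joint_j", k)], ctx.R[j]),
                    (layout[("mrp", i)], -ctx.d_Rv_dchi(i, Jani)),
                    (layout[("mrp", j)], ctx.d_Rv_dchi(j, Janj)),
                ]
            add("joint_pos", (i, j), r, blocks, config.sigma_joint_pos)
        if config.use_joint_velocity_model:
            wi = layout.get(mean, ("omega", i))
            wj = layout.get(mean, ("omega", j))
            ui = np.cross(wi, Jani)
            uj = np.cross(wj, Janj)
            r = -(
                layout.get(mean, ("vel", i)) + ctx.R[i] @ ui
                - layout.get(mean, ("vel", j)) - ctx.R[j] @ uj
            )
            blocks = []
            if with_jacobian:
                blocks = [
                    (layout[("vel", i)], -I3),
                    (layout[("vel", j)], I3),
                    (layout[("omega", i)], ctx.R[i] @ skew(Jani)),
                    (layout[("omega", j)], -ctx.R[j] @ skew(Janj)),
                    (layout[("joint_i", k)], -ctx.R[i] @ skew(wi)),
                    (layout[("joint_j", k)], ctx.R[j] @ skew(wj)),
                    (layout[("mrp", i)], -ctx.d_Rv_dchi(i, ui)),
                    (layout[("mrp", j)], ctx.d_Rv_dchi(j, uj)),
                ]
            add("joint_vel", (i, j), r, blocks, config.sigma_joint_vel)
        if config.use_accel_level_joint_model and prev_omega is not None:
            r = accel_level_joint_residual(mean, layout, k, prev_omega, config.dt)
            blocks = []
            if with_jacobian:
                blocks = _accel_level_blocks(mean, layout, k, prev_omega, config, ctx)
            add("joint_acc", (i, j), r, blocks, np.eye(3))

    if config.use_fixed_point:
        for l in topology.fixed_imus:
            Jfix = layout.get(mean, ("fix", l))
            r = topology.fixed_point(l) - layout.get(mean, ("pos", l)) - ctx.R[l] @ Jfix
            blocks = []
            if with_jacobian:
                blocks = [
                    (layout[("pos", l)], -I3),
                    (layout[("fix", l)], -ctx.R[l]),
                    (layout[("mrp", l)], -ctx.d_Rv_dchi(l, Jfix)),
                ]
            add("fixed", l, r, blocks, config.sigma_fix)

    if config.use_zupt and frame.zupt is not None:
        for c in np.flatnonzero(frame.zupt):
            r = -layout.get(mean, ("vel", int(c)))
            blocks = [(layout[("vel", int(c))], -I3)] if with_jacobian else []
            add("zupt", int(c), r, blocks, config.sigma_zupt)

    m = sum(r.shape[0] for r in rows)
    r_all = np.concatenate(rows)
    sigma = np.zeros((m, m))
    jac = np.zeros((m, layout.dim)) if with_jacobian else None
    off = 0
    for r, blocks, s in zip(rows, jacs, sigmas):
        n = r.shape[0]
        sigma[off : off + n, off : off + n] = s
        if with_jacobian:
            for col, block in blocks:
                jac[off : off + n, col] = block
        off += n
    return StackedObservation(r=r_all, jac=jac, sigma=sigma, labels=labels)


def _accel_level_blocks(mean, layout, k, prev_omega, config, ctx):
    """FD Jacobian blocks of the ablation model (not a hot path)."""
    i, j = layout.topology.joints[k]
    dt = config.dt
    blocks = []

    def fd(key):
        s = layout[key]
        out = np.empty((3, 3))
        for c in range(3):
            h = config.fd_step * max(1.0, abs(mean[s.start + c]))
            mp, mm = mean.copy(), mean.copy()
            mp[s.start + c] += h
            mm[s.start + c] -= h
            out[:, c] = (
                accel_level_joint_residual(mp, layout, k, prev_omega, dt)
                - accel_level_joint_residual(mm, layout, k, prev_omega, dt)
            ) / (2.0 * h)
        return s, out

    for key in (
        ("acc", i), ("acc", j), ("omega", i), ("omega", j),
        ("mrp", i), ("mrp", j), ("joint_i", k), ("joint_j", k),
    ):
        blocks.append(fd(key))
    return blocks


# ---------------------------------------------------------------------------
# SHOE zero-velocity detector

def shoe_statistic(
    acc_win: np.ndarray,
    gyro_win: np.ndarray,
    var_a: float,
    var_w: float,
    gravity: float = 9.81,
) -> float:
    """Stance-hypothesis-optimal detector statistic over one window.

    ``T = 1/b * sum_k(|y_a,k - g * mean_dir|^2 / var_a + |y_w,k|^2 / var_w)``
    where ``mean_dir`` is the direction of the window-mean accelerometer
    sample.  Small values indicate a stationary IMU.
    """
    acc_win = np.asarray(acc_win, dtype=float)
    gyro_win = np.asarray(gyro_win, dtype=float)
    b = acc_win.shape[0]
    mean_a = acc_win.mean(axis=0)
    n = np.linalg.norm(mean_a)
    g_ref = gravity * mean_a / n if n > 0 else np.zeros(3)
    ta = np.sum((acc_win - g_ref) ** 2) / var_a
    tw = np.sum(gyro_win**2) / var_w
    return float((ta + tw) / b)


def shoe_detect(
    windows: dict[int, tuple[np.ndarray, np.ndarray]],
    config: EstimatorConfig,
) -> tuple[int | None, dict[int, float]]:
    """Evaluate the SHOE statistic per candidate and keep at most one flag.

    ``windows`` maps candidate IMU index to ``(acc_window, gyro_window)``
    arrays of shape ``(b, 3)``.  Candidates whose window is not yet full
    are ignored.  Among candidates below the threshold only the one with
    the lowest statistic is returned.
    """
    stats: dict[int, float] = {}
    for c, (aw, gw) in windows.items():
        aw = np.asarray(aw)
        if aw.shape[0] < config.shoe_window:
            continue
        stats[c] = shoe_statistic(
            aw, gw, config.shoe_var_a, config.shoe_var_w, config.gravity
        )
    below = {c: t for c, t in stats.items() if t < config.shoe_threshold}
    if not below:
        return None, stats
    return min(below, key=below.get), stats
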