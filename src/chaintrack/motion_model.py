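"""Deterministic state transition, its Jacobian, and the process covariance.

The per-IMU motion model assumes constant linear acceleration and constant
angular velocity over one sampling interval: position/velocity integrate
exactly under that assumption, the orientation MRP advances through the
quaternion exponential of ``dt/2 * omega``, and joint / fixed-point offsets
are constants.  Process noise enters only on the angular-velocity and
acceleration blocks (scaled by dt in the transition, hence ``dt^2 * Q``
discrete covariance); every other row/column of the process covariance is
exactly zero, which is what keeps the parameter estimates consistent.
"""

from __future__ import annotations

import numpy as np

from .chain_model import EstimatorConfig, StateLayout
from .rotations import mrp_shadow, mrp_to_quat, quat_exp, quat_multiply, quat_to_mrp

__all__ = ["propagate", "process_covariance", "motion_jacobian", "propagate_mrp"]


def propagate_mrp(chi: np.ndarray, omega: np.ndarray, dt: float) -> np.ndarray:
    """Advance an orientation MRP by a constant body angular rate."""
    q = quat_multiply(mrp_to_quat(chi), quat_exp(0.5 * dt * omega))
    return mrp_shadow(quat_to_mrp(q))


def propagate(mean: np.ndarray, layout: StateLayout, dt: float) -> np.ndarray:
    """Apply the constant-acceleration / constant-rate transition to a mean."""
    if not np.all(np.isfinite(mean)):
        raise ValueError("non-finite state mean")
    out = mean.copy()
    for i in range(layout.n_imus):
        omega = layout.get(mean, ("omega", i))
        acc = layout.get(mean, ("acc", i))
        vel = layout.get(mean, ("vel", i))
        pos = layout.get(mean, ("pos", i))
        chi = layout.get(mean, ("mrp", i))
        layout.set(out, ("pos", i), pos + dt * vel + 0.5 * dt * dt * acc)
        layout.set(out, ("vel", i), vel + dt * acc)
        layout.set(out, ("mrp", i), propagate_mrp(chi, omega, dt))
        # omega, acc, joint and fixed parameters carry over unchanged
    return out


def process_covariance(layout: StateLayout, config: EstimatorConfig, dt: float | None = None) -> np.ndarray:
    """Discrete process covariance: ``dt^2 Q`` on omega/acc blocks, zero elsewhere."""
    if dt is None:
        dt = config.dt
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    Q = np.zeros((layout.dim, layout.dim))
    for i in range(layout.n_imus):
        so = layout[("omega", i)]
        sa = layout[("acc", i)]
        Q[so, so] = dt * dt * config.q_omega
        Q[sa, sa] = dt * dt * config.q_acc
    return Q


def motion_jacobian(
    mean: np.ndarray, layout: StateLayout, dt: float, fd_step: float = 1e-6
) -> np.ndarray:
    """Jacobian of :func:`propagate` at ``mean``.

    The integrator rows are exact (identity, ``dt I``, ``dt^2/2 I``); the
    orientation rows are obtained by central finite differences of the MRP
    propagation with respect to the MRP and angular-velocity blocks.
    """
    F = np.eye(layout.dim)
    I3 = np.eye(3)
    for i in range(layout.n_imus):
        sp = layout[("pos", i)]
        sv = layout[("vel", i)]
        sa = layout[("acc", i)]
        sm = layout[("mrp", i)]
        so = layout[("omega", i)]
        F[sp, sv] = dt * I3
        F[sp, sa] = 0.5 * dt * dt * I3
        F[sv, sa] = dt * I3
        chi = layout.get(mean, ("mrp", i)).copy()
        omega = layout.get(mean, ("omega", i)).copy()
        F[sm, sm] = 0.0
        for k in range(3):
            h = fd_step * max(1.0, abs(chi[k]))
            cp, cm = chi.copy(), chi.copy()
            cp[k] += h
            cm[k] -= h
            F[sm, sm.start + k] = (propagate_mrp(cp, omega, dt) - propagate_mrp(cm, omega, dt)) / (2 * h)
        for k in range(3):
            h = fd_step * max(1.0, abs(omega[k]))
            op, om = omega.copy(), omega.copy()
            op[k] += h
            om[k] -= h
            F[sm, so.start + k] = (propagate_mrp(chi, op, dt) - propagate_mrp(chi, om, dt)) / (2 * h)
    return F
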