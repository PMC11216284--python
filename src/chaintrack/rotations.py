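"""Self-contained rotation algebra for attitude estimation.

Conventions used throughout the package:

* Hamilton quaternions, scalar first: ``q = (q0, q1, q2, q3)`` with ``q0``
  the scalar part.  ``quat_to_matrix(q)`` returns the body-to-navigation
  rotation ``R^{NI}``: a vector right-multiplied to it is transformed from
  the IMU frame into the navigation frame.
* Navigation frame: z-axis up, gravity ``g^N = (0, 0, -9.81)`` m/s^2,
  x-axis toward magnetic north.  A level, stationary IMU therefore measures
  specific force ``(0, 0, +9.81)``.
* Modified Rodrigues Parameters (MRP): ``chi = q_vec / (1 + q0)``, a
  three-parameter chart on SO(3).  The shadow set ``-chi / |chi|^2`` is
  used whenever ``|chi| > 1`` so the representation never approaches the
  360 degree singularity.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "skew",
    "quat_normalize",
    "quat_multiply",
    "quat_conjugate",
    "quat_exp",
    "quat_log",
    "quat_to_matrix",
    "matrix_to_quat",
    "mrp_to_quat",
    "quat_to_mrp",
    "mrp_to_matrix",
    "mrp_shadow",
    "rotation_angle",
    "triad_orientation",
]

_IDENTITY_QUAT = np.array([1.0, 0.0, 0.0, 0.0])


def skew(v: np.ndarray) -> np.ndarray:
    """Cross-product matrix ``[v x]`` such that ``skew(v) @ w == np.cross(v, w)``."""
    return np.array(
        [
            [0.0, -v[2], v[1]],
            [v[2], 0.0, -v[0]],
            [-v[1], v[0], 0.0],
        ]
    )


def quat_normalize(q: np.ndarray) -> np.ndarray:
    """Return the unit quaternion on the q0 >= 0 hemisphere."""
    n = np.linalg.norm(q)
    if n == 0.0 or not np.isfinite(n):
        raise ValueError("cannot normalize zero or non-finite quaternion")
    q = q / n
    if q[0] < 0.0:
        q = -q
    return q


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    out = q.copy()
    out[1:] = -out[1:]
    return out


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a (.) b, renormalized.

    Composition convention matches the rotation matrices:
    ``quat_to_matrix(a (.) b) == quat_to_matrix(a) @ quat_to_matrix(b)``.
    """
    a0, av = a[0], a[1:]
    b0, bv = b[0], b[1:]
    out = np.empty(4)
    out[0] = a0 * b0 - av @ bv
    out[1:] = a0 * bv + b0 * av + np.cross(av, bv)
    return quat_normalize(out)


def quat_exp(v: np.ndarray) -> np.ndarray:
    """Quaternion exponential of a 3-vector: ``(cos|v|, sin|v| * v/|v|)``.

    ``quat_exp(dt/2 * omega)`` is the incremental rotation of an angular
    rate ``omega`` held for ``dt`` (rotation angle ``|omega| * dt``).
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite rotation increment")
    a = np.linalg.norm(v)
    out = np.empty(4)
    if a < 1e-8:
        # Taylor limit: sin(a)/a = 1 - a^2/6
        out[0] = 1.0 - 0.5 * a * a
        out[1:] = v * (1.0 - a * a / 6.0)
    else:
        out[0] = np.cos(a)
        out[1:] = np.sin(a) / a * v
    return quat_normalize(out)


def quat_log(q: np.ndarray) -> np.ndarray:
    """Inverse of :func:`quat_exp` (principal branch, |result| <= pi/2)."""
    q = quat_normalize(q)
    s = np.linalg.norm(q[1:])
    if s < 1e-12:
        return q[1:].copy()
    a = np.arctan2(s, q[0])
    return q[1:] * (a / s)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    q0, q1, q2, q3 = q
    return np.array(
        [
            [1 - 2 * (q2 * q2 + q3 * q3), 2 * (q1 * q2 - q0 * q3), 2 * (q1 * q3 + q0 * q2)],
            [2 * (q1 * q2 + q0 * q3), 1 - 2 * (q1 * q1 + q3 * q3), 2 * (q2 * q3 - q0 * q1)],
            [2 * (q1 * q3 - q0 * q2), 2 * (q2 * q3 + q0 * q1), 1 - 2 * (q1 * q1 + q2 * q2)],
        ]
    )


def matrix_to_quat(R: np.ndarray) -> np.ndarray:
    """Rotation matrix to unit quaternion (Shepperd's method)."""
    tr = np.trace(R)
    if tr > 0.0:
        s = np.sqrt(tr + 1.0) * 2.0
        q = np.array(
            [0.25 * s, (R[2, 1] - R[1, 2]) / s, (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(max(R[i, i] - R[j, j] - R[k, k] + 1.0, 0.0)) * 2.0
        q = np.empty(4)
        q[0] = (R[k, j] - R[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (R[j, i] + R[i, j]) / s
        q[1 + k] = (R[k, i] + R[i, k]) / s
    return quat_normalize(q)


def mrp_to_quat(chi: np.ndarray) -> np.ndarray:
    n2 = float(chi @ chi)
    q = np.empty(4)
    q[0] = (1.0 - n2) / (1.0 + n2)
    q[1:] = 2.0 * chi / (1.0 + n2)
    return quat_normalize(q)


def quat_to_mrp(q: np.ndarray) -> np.ndarray:
    """MRP ``chi = q_vec / (1 + q0)``, on the |chi| <= 1 branch."""
    q = quat_normalize(q)  # hemisphere flip avoids the q0 = -1 singularity
    return q[1:] / (1.0 + q[0])


def mrp_to_matrix(chi: np.ndarray) -> np.ndarray:
    return quat_to_matrix(mrp_to_quat(chi))


def mrp_shadow(chi: np.ndarray) -> np.ndarray:
    """Switch to the shadow set when |chi| > 1 (keeps |chi| <= 1)."""
    n2 = float(chi @ chi)
    if n2 > 1.0:
        return -chi / n2
    return chi


def rotation_angle(R: np.ndarray) -> float:
    """Rotation angle ``phi(R) = arccos((trace(R) - 1) / 2)`` in [0, pi]."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def triad_orientation(
    y_a: np.ndarray,
    y_m: np.ndarray,
    gravity: float = 9.81,
    min_angle_deg: float = 5.0,
) -> np.ndarray:
    """Attitude of a stationary IMU from one accelerometer/magnetometer sample.

    Standard triad construction with the measured specific force (gravity
    reaction, pointing up in the IMU frame) as primary axis and the
    magnetometer as secondary.  Returns ``R^{NI}`` such that the rotated
    accelerometer aligns with up and the rotated magnetic field has zero
    y-component with positive x (the navigation x-axis points toward
    magnetic north).

    Parameters
    ----------
    y_a:
        Accelerometer sample in m/s^2 (approximately ``R^T (0, 0, +g)``).
    y_m:
        Magnetometer sample, arbitrary units.
    """
    y_a = np.asarray(y_a, dtype=float)
    y_m = np.asarray(y_m, dtype=float)
    na = np.linalg.norm(y_a)
    nm = np.linalg.norm(y_m)
    if na == 0.0 or nm == 0.0:
        raise ValueError("triad requires non-zero accelerometer and magnetometer samples")
    if not (0.5 * gravity <= na <= 1.5 * gravity):
        warnings.warn(
            f"accelerometer norm {na:.2f} m/s^2 far from 1 g; IMU may not be stationary",
            stacklevel=2,
        )
    cos_ang = np.clip((y_a @ y_m) / (na * nm), -1.0, 1.0)
    angle_deg = np.degrees(np.arccos(abs(cos_ang)))  # angle to the nearest (anti-)parallel
    if angle_deg < min_angle_deg:
        raise ValueError("degenerate triad: accelerometer and magnetometer nearly parallel")

    t1b = y_a / na
    t2b = np.cross(t1b, y_m)
    t2b /= np.linalg.norm(t2b)
    t3b = np.cross(t1b, t2b)
    body = np.column_stack([t1b, t2b, t3b])
    # navigation-side triad: up, up x north, up x (up x north)
    nav = np.array([[0.0, 0.0, -1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
    R = nav @ body.T
    # orthonormalize against accumulated round-off
    u, _, vt = np.linalg.svd(R)
    return u @ vt
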