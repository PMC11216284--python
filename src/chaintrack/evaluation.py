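"""Evaluation metrics for chain tracking runs.

Segment lengths and their errors, joint end-point errors, relative/global
orientation angle errors, RMSE aggregation over an index set, ordinary
least products (OLP, reduced-major-axis) regression for bias/drift
detection, and the coefficient of determination R^2 against the identity
line.  Series helpers compare a :class:`~chaintrack.estimator.TrackingResult`
against a simulator :class:`~chaintrack.simulator.GroundTruth`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .rotations import matrix_to_quat, quat_log, rotation_angle

__all__ = [
    "segment_length",
    "segment_length_error",
    "joint_endpoint_error",
    "relative_angle_error",
    "rmse",
    "olp_fit",
    "r_squared",
    "reduced_angles",
    "joint_endpoint_error_series",
    "segment_length_series",
    "segment_length_error_series",
    "global_angle_error_series",
    "relative_angle_error_series",
    "relative_rotation_series",
    "convergence_sample",
    "write_report",
]


def segment_length(j_a: np.ndarray, j_b: np.ndarray) -> float:
    """Distance between two joint positions expressed in the same IMU frame."""
    return float(np.linalg.norm(np.asarray(j_a, dtype=float) - np.asarray(j_b, dtype=float)))


def segment_length_error(sl: float, sl_ref: float) -> float:
    """Absolute segment-length error against a reference length (m)."""
    return abs(float(sl) - float(sl_ref))


def joint_endpoint_error(j_est: np.ndarray, j_ref: np.ndarray) -> float:
    """Euclidean distance between estimated and reference joint position (m)."""
    return float(np.linalg.norm(np.asarray(j_est, dtype=float) - np.asarray(j_ref, dtype=float)))


def relative_angle_error(r_est: np.ndarray, r_ref: np.ndarray) -> float:
    """Angle (degrees) between two rotations expressed in the same frames."""
    return float(np.degrees(rotation_angle(np.asarray(r_est) @ np.asarray(r_ref).T)))


def rmse(errors: np.ndarray) -> float:
    """Root mean square over time of the summed squared errors per step.

    ``errors`` has shape (T,) or (T, m): the inner sum runs over the index
    set (columns), the mean over time (rows).
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("rmse of empty error array")
    if errors.ndim == 1:
        errors = errors[:, None]
    return float(np.sqrt(np.mean(np.sum(errors**2, axis=1))))


def olp_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ordinary least products (reduced major axis) regression.

    Returns ``(intercept, slope)`` with
    ``slope = sign(cov(x, y)) * sqrt(var(y) / var(x))``.  A slope of 1 and
    intercept of 0 indicate agreement free of proportional and fixed bias.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("olp_fit needs two equal-length 1-d series, n >= 3")
    vx = np.var(x)
    vy = np.var(y)
    if vx == 0.0 or vy == 0.0:
        raise ValueError("olp_fit requires non-zero variance in both series")
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    slope = float(np.sign(cov) if cov != 0 else 1.0) * float(np.sqrt(vy / vx))
    intercept = float(y.mean() - slope * x.mean())
    return intercept, slope


def r_squared(x_ref: np.ndarray, y_est: np.ndarray) -> float:
    """Coefficient of determination against the identity line.

    Residuals are ``y_est - x_ref`` (agreement, not a refitted line), so a
    perfect estimator scores 1 and any bias lowers the score.
    """
    x_ref = np.asarray(x_ref, dtype=float)
    y_est = np.asarray(y_est, dtype=float)
    if x_ref.shape != y_est.shape or x_ref.size < 2:
        raise ValueError("r_squared needs two equal-length series, n >= 2")
    ss_tot = float(np.sum((x_ref - x_ref.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r_squared requires non-zero variance of the reference")
    ss_res = float(np.sum((y_est - x_ref) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# angle reduction for OLP / R^2

def _rotvec(R: np.ndarray) -> np.ndarray:
    return 2.0 * quat_log(matrix_to_quat(R))


def reduced_angles(
    rot_est: np.ndarray, rot_ref: np.ndarray, axis: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce two rotation series to signed single-angle series.

    The dominant rotation axis is the principal direction (first right
    singular vector) of the reference rotation vectors; each rotation is
    reduced to the signed projection of its rotation vector onto that
    axis.  Pass ``axis`` to override the automatic choice.
    """
    v_ref = np.stack([_rotvec(R) for R in np.asarray(rot_ref)])
    v_est = np.stack([_rotvec(R) for R in np.asarray(rot_est)])
    if axis is None:
        _, _, vt = np.linalg.svd(v_ref - v_ref.mean(axis=0), full_matrices=False)
        axis = vt[0]
        if np.mean(v_ref @ axis) < 0:
            axis = -axis
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return v_est @ axis, v_ref @ axis


# ---------------------------------------------------------------------------
# series helpers against ground truth

def joint_endpoint_error_series(result, truth) -> np.ndarray:
    """(T, 2 * n_joints) end-point errors of every joint offset estimate."""
    n_j = len(result.topology.joints)
    out = np.empty((result.n_steps, 2 * n_j))
    for k in range(n_j):
        est_i = result.block_series(("joint_i", k))
        est_j = result.block_series(("joint_j", k))
        out[:, 2 * k] = np.linalg.norm(est_i - truth.joint_local_i[k], axis=1)
        out[:, 2 * k + 1] = np.linalg.norm(est_j - truth.joint_local_j[k], axis=1)
    return out


def _computable_segments(topology):
    """Segments whose two bounding joint offsets live in the same IMU frame.

    Yields ``(imu, key_a, key_b)`` where the keys index the two joint-offset
    blocks expressed in that IMU's frame (fixed-point offsets included).
    """
    per_imu: dict[int, list[tuple]] = {}
    for k, (i, j) in enumerate(topology.joints):
        per_imu.setdefault(i, []).append(("joint_i", k))
        per_imu.setdefault(j, []).append(("joint_j", k))
    for l in topology.fixed_imus:
        per_imu.setdefault(l, []).append(("fix", l))
    for imu, keys in sorted(per_imu.items()):
        if len(keys) == 2:
            yield imu, keys[0], keys[1]


def segment_length_series(result) -> dict[int, np.ndarray]:
    """Per-computable-segment estimated length series (m), keyed by IMU index."""
    out = {}
    for imu, ka, kb in _computable_segments(result.topology):
        a = result.block_series(ka)
        b = result.block_series(kb)
        out[imu] = np.linalg.norm(a - b, axis=1)
    return out


def segment_length_error_series(result, truth) -> dict[int, np.ndarray]:
    """Per-segment |estimated - true| length series (m)."""
    lengths = segment_length_series(result)
    return {
        imu: np.abs(series - truth.segment_lengths[imu])
        for imu, series in lengths.items()
    }


def global_angle_error_series(result, truth) -> np.ndarray:
    """(T, N) angle errors (degrees) of the global IMU orientations."""
    T, N = result.n_steps, result.topology.n_imus
    out = np.empty((T, N))
    for i in range(N):
        est = result.rotations(i)
        for k in range(T):
            out[k, i] = np.degrees(rotation_angle(est[k] @ truth.rot[k, i].T))
    return out


def relative_rotation_series(rotations_by_imu, pair) -> np.ndarray:
    """(T, 3, 3) series of R^{I_i I_j} from per-IMU global rotation series."""
    i, j = pair
    Ri = rotations_by_imu[i]
    Rj = rotations_by_imu[j]
    return np.einsum("tba,tbc->tac", Ri, Rj)  # R_i^T R_j per step


def relative_angle_error_series(result, truth) -> np.ndarray:
    """(T, n_joints) angle errors (degrees) of the relative IMU orientations."""
    est_rots = {i: result.rotations(i) for i in range(result.topology.n_imus)}
    true_rots = {i: truth.rot[:, i] for i in range(result.topology.n_imus)}
    T = result.n_steps
    out = np.empty((T, len(result.topology.joints)))
    for kj, pair in enumerate(result.topology.joints):
        rel_est = relative_rotation_series(est_rots, pair)
        rel_ref = relative_rotation_series(true_rots, pair)
        for k in range(T):
            out[k, kj] = np.degrees(rotation_angle(rel_est[k] @ rel_ref[k].T))
    return out


def convergence_sample(errors: np.ndarray, threshold: float) -> int | None:
    """First step after which every error column stays below ``threshold``.

    Returns ``None`` when some error is still above the threshold at the
    final step.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.ndim == 1:
        errors = errors[:, None]
    bad = np.any(errors >= threshold, axis=-1)
    if bad[-1]:
        return None
    idx = np.flatnonzero(bad)
    return int(idx[-1]) + 1 if idx.size else 0


# ---------------------------------------------------------------------------
# report output

def write_report(out_dir, result, truth=None) -> dict:
    """Write per-joint/segment metric tables (CSV) and a JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"n_steps": int(result.n_steps)}

    lengths = segment_length_series(result)
    rows = []
    for imu, series in lengths.items():
        rows.append(
            {
                "segment_imu": imu,
                "final_length_m": float(series[-1]),
                "mean_length_m": float(series.mean()),
            }
        )
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / "segment_lengths.csv", index=False)
    summary["final_segment_lengths_m"] = {str(r["segment_imu"]): r["final_length_m"] for r in rows}

    unc_rows = []
    for kj, pair in enumerate(result.topology.joints):
        unc_rows.append(
            {
                "joint": f"{pair[0]}-{pair[1]}",
                "final_uncertainty_m": float(result.joint_uncertainty[-1, kj]),
            }
        )
    if unc_rows:
        pd.DataFrame(unc_rows).to_csv(out_dir / "joint_uncertainty.csv", index=False)
    summary["final_joint_uncertainty_m"] = {
        r["joint"]: r["final_uncertainty_m"] for r in unc_rows
    }

    if truth is not None:
        err = joint_endpoint_error_series(result, truth)
        seg_err = segment_length_error_series(result, truth)
        ang = relative_angle_error_series(result, truth)
        summary["final_joint_endpoint_errors_m"] = [float(e) for e in err[-1]]
        summary["final_segment_length_errors_m"] = {
            str(imu): float(s[-1]) for imu, s in seg_err.items()
        }
        summary["relative_angle_rmse_deg"] = {
            f"{pair[0]}-{pair[1]}": float(rmse(ang[:, kj]))
            for kj, pair in enumerate(result.topology.joints)
        }
        conv = convergence_sample(err, 0.02)
        summary["convergence_sample_2cm"] = conv if conv is None else int(conv)

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
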