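"""Kinematic-chain topology, state-vector layout and estimator configuration.

The estimated state is split into two groups:

* ``X1`` — blocks driven by process noise: per IMU the angular velocity
  ``omega^{NI_i}_{I_i}`` (rad/s, IMU frame) and the linear acceleration
  ``Idd_i^N`` (m/s^2, navigation frame).
* ``X2`` — noise-free blocks that follow the motion model exactly: per IMU
  the orientation MRP ``chi^{NI_i}``, position ``I_i^N`` and velocity
  ``Id_i^N``; then per joint the two IMU-local joint offsets
  ``J_{i,j}^{I_i}``, ``J_{i,j}^{I_j}``; then per anchored IMU the local
  fixed-point offset ``J_fix^{I_l}``.

All blocks are 3-dimensional, so the state dimension is
``6 N_I + 9 N_I + 6 |joints| + 3 |fixed|``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ChainTopology",
    "StateLayout",
    "StateEstimate",
    "EstimatorConfig",
    "build_layout",
    "default_config",
    "topology_to_dict",
    "topology_from_dict",
    "config_to_dict",
    "config_from_dict",
]


def _as_cov(value, name: str) -> np.ndarray:
    """Accept a scalar variance or a full 3x3 covariance; validate SPD."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = float(arr) * np.eye(3)
    if arr.shape != (3, 3):
        raise ValueError(f"{name}: expected scalar or 3x3 covariance, got shape {arr.shape}")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError(f"{name}: covariance must be symmetric")
    if np.linalg.eigvalsh(arr)[0] <= 0.0:
        raise ValueError(f"{name}: covariance must be positive definite")
    return arr


@dataclass(frozen=True)
class ChainTopology:
    """IMU network: sensors, connecting joints, anchors and ZUPT candidates.

    Parameters
    ----------
    imu_ids:
        Ordered sensor names; state-layout IMU indices follow this order.
    joints:
        Pairs of IMU indices ``(i, j)`` connected by a 3-DoF joint.
    fixed_imus:
        IMU indices assumed to move around a known navigation-frame point.
    zupt_candidates:
        IMU indices eligible for zero-velocity detections (e.g. feet).
    fixed_point_nav:
        Navigation-frame anchor point per fixed IMU (defaults to origin).
    """

    imu_ids: tuple[str, ...]
    joints: tuple[tuple[int, int], ...] = ()
    fixed_imus: tuple[int, ...] = ()
    zupt_candidates: tuple[int, ...] = ()
    fixed_point_nav: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "imu_ids", tuple(str(s) for s in self.imu_ids))
        object.__setattr__(
            self, "joints", tuple((int(i), int(j)) for i, j in self.joints)
        )
        object.__setattr__(self, "fixed_imus", tuple(int(i) for i in self.fixed_imus))
        object.__setattr__(
            self, "zupt_candidates", tuple(int(i) for i in self.zupt_candidates)
        )
        n = len(self.imu_ids)
        if n == 0:
            raise ValueError("topology needs at least one IMU")
        if len(set(self.imu_ids)) != n:
            raise ValueError("duplicate IMU ids")
        for i, j in self.joints:
            if i == j:
                raise ValueError(f"joint ({i}, {j}) must reference two distinct IMUs")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"joint ({i}, {j}) references a non-existing IMU")
        for i in self.fixed_imus + self.zupt_candidates:
            if not (0 <= i < n):
                raise ValueError(f"IMU index {i} out of range")
        if self.joints and n <= 1:
            raise ValueError("a jointed chain needs more than one IMU")
        anchors = self.fixed_point_nav
        if not anchors:
            anchors = tuple((0.0, 0.0, 0.0) for _ in self.fixed_imus)
        if len(anchors) != len(self.fixed_imus):
            raise ValueError("fixed_point_nav must match fixed_imus")
        object.__setattr__(
            self,
            "fixed_point_nav",
            tuple(tuple(float(x) for x in p) for p in anchors),
        )

    @property
    def n_imus(self) -> int:
        return len(self.imu_ids)

    def fixed_point(self, l: int) -> np.ndarray:
        """Navigation-frame anchor of fixed IMU ``l``."""
        return np.array(self.fixed_point_nav[self.fixed_imus.index(l)])

    def is_connected(self) -> bool:
        """True when the IMU/joint graph is connected."""
        n = self.n_imus
        if n == 1:
            return True
        adj: dict[int, list[int]] = {i: [] for i in range(n)}
        for i, j in self.joints:
            adj[i].append(j)
            adj[j].append(i)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == n


class StateLayout:
    """Deterministic index ranges of every state block.

    Block keys are ``("omega", i)``, ``("acc", i)`` (the X1 part, in IMU
    order), then ``("mrp", i)``, ``("pos", i)``, ``("vel", i)``,
    ``("joint_i", k)``, ``("joint_j", k)`` (k-th joint, offset in frame
    I_i / I_j) and ``("fix", l)``.
    """

    def __init__(self, topology: ChainTopology):
        if not topology.is_connected():
            raise ValueError("topology graph of IMUs and joints is not connected")
        self.topology = topology
        self.blocks: dict[tuple, slice] = {}
        off = 0

        def add(key):
            nonlocal off
            self.blocks[key] = slice(off, off + 3)
            off += 3

        for i in range(topology.n_imus):
            add(("omega", i))
            add(("acc", i))
        self.n_x1 = off
        for i in range(topology.n_imus):
            add(("mrp", i))
            add(("pos", i))
            add(("vel", i))
        for k in range(len(topology.joints)):
            add(("joint_i", k))
            add(("joint_j", k))
        for l in topology.fixed_imus:
            add(("fix", l))
        self.dim = off

    def __getitem__(self, key: tuple) -> slice:
        return self.blocks[key]

    def get(self, vec: np.ndarray, key: tuple) -> np.ndarray:
        return vec[self.blocks[key]]

    def set(self, vec: np.ndarray, key: tuple, value) -> None:
        vec[self.blocks[key]] = value

    def keys(self) -> Iterable[tuple]:
        return self.blocks.keys()

    @property
    def n_imus(self) -> int:
        return self.topology.n_imus


def build_layout(topology: ChainTopology) -> StateLayout:
    """Build the split-state layout; deterministic for a given topology."""
    return StateLayout(topology)


class EstimationError(RuntimeError):
    """Raised when the estimator loses numerical validity (non-PSD covariance,
    singular innovation, broken input stream)."""


@dataclass
class StateEstimate:
    """Gaussian state estimate: mean vector and covariance over a layout."""

    mean: np.ndarray
    cov: np.ndarray
    layout: StateLayout
    t: float = 0.0

    def copy(self) -> "StateEstimate":
        return StateEstimate(self.mean.copy(), self.cov.copy(), self.layout, self.t)

    def block(self, key: tuple) -> np.ndarray:
        return self.layout.get(self.mean, key)

    def marginal(self, key: tuple) -> np.ndarray:
        s = self.layout[key]
        return self.cov[s, s]

    def validate(self, atol_factor: float = 1e-9) -> None:
        if not np.all(np.isfinite(self.mean)) or not np.all(np.isfinite(self.cov)):
            raise EstimationError("non-finite state estimate")
        if not np.allclose(self.cov, self.cov.T, atol=1e-9):
            raise EstimationError("covariance not symmetric")
        tr = float(np.trace(self.cov))
        lo = float(np.linalg.eigvalsh(self.cov)[0])
        if lo < -atol_factor * max(tr, 1.0):
            raise EstimationError(f"covariance not PSD (lambda_min={lo:.3e}, trace={tr:.3e})")


@dataclass
class EstimatorConfig:
    """All covariances, model toggles and solver settings of the estimator.

    Covariance defaults are the values used throughout the experimental
    evaluation; any entry accepts either a scalar variance (isotropic) or a
    full 3x3 matrix.
    """

    # process noise (continuous rates entering scaled by dt)
    q_acc: np.ndarray = 3e5
    q_omega: np.ndarray = 1e4
    # measurement noise
    sigma_acc: np.ndarray = 1e-2
    sigma_gyro: np.ndarray = 1e-3
    sigma_mag: np.ndarray = 1e-2
    sigma_joint_pos: np.ndarray = 1e-4
    sigma_joint_vel: np.ndarray = 1e-3
    sigma_fix: np.ndarray = 1e-4
    sigma_zupt: np.ndarray = 1e-4
    # initial priors
    sigma_init_vel: np.ndarray = 1.0
    sigma_init_acc: np.ndarray = 1.0
    sigma_init_omega: np.ndarray = 1.0
    sigma_init_mrp: np.ndarray = 1e-6
    sigma_init_pos: np.ndarray = 1.0
    sigma_init_joint: np.ndarray = 1.6e-1
    # sampling
    dt: float = 0.01
    gravity: float = 9.81
    # model toggles
    use_magnetometer: bool = True
    use_joint_position_model: bool = True
    use_joint_velocity_model: bool = True
    use_fixed_point: bool = True
    use_zupt: bool = True
    use_accel_level_joint_model: bool = False
    # Gauss-Newton solver
    gn_max_iter: int = 10
    gn_step_tol: float = 1e-8
    armijo_c: float = 1e-4
    armijo_max_halvings: int = 20
    fd_step: float = 1e-6
    h_at_converged_mean: bool = False
    # SHOE zero-velocity detector
    shoe_window: int = 11
    shoe_threshold: float = 50.0
    shoe_sigma_a2: float | None = None  # defaults to mean diagonal of sigma_acc
    shoe_sigma_w2: float | None = None  # defaults to mean diagonal of sigma_gyro
    # reproducibility
    seed: int = 0

    _COV_FIELDS = (
        "q_acc",
        "q_omega",
        "sigma_acc",
        "sigma_gyro",
        "sigma_mag",
        "sigma_joint_pos",
        "sigma_joint_vel",
        "sigma_fix",
        "sigma_zupt",
        "sigma_init_vel",
        "sigma_init_acc",
        "sigma_init_omega",
        "sigma_init_mrp",
        "sigma_init_pos",
        "sigma_init_joint",
    )

    def __post_init__(self):
        for name in self._COV_FIELDS:
            setattr(self, name, _as_cov(getattr(self, name), name))
        if self.dt <= 0.0:
            raise ValueError("dt must be positive")
        if self.shoe_window < 2:
            raise ValueError("SHOE window must span at least 2 samples")

    @property
    def shoe_var_a(self) -> float:
        if self.shoe_sigma_a2 is not None:
            return float(self.shoe_sigma_a2)
        return float(np.mean(np.diag(self.sigma_acc)))

    @property
    def shoe_var_w(self) -> float:
        if self.shoe_sigma_w2 is not None:
            return float(self.shoe_sigma_w2)
        return float(np.mean(np.diag(self.sigma_gyro)))

    def replace(self, **kw) -> "EstimatorConfig":
        return replace(self, **kw)


def default_config(**overrides) -> EstimatorConfig:
    """Estimator configuration with the default covariance settings."""
    return EstimatorConfig(**overrides)


# ---------------------------------------------------------------------------
# serialization (one YAML/JSON-able document for topology + config)

def topology_to_dict(topology: ChainTopology) -> dict:
    return {
        "imu_ids": list(topology.imu_ids),
        "joints": [list(j) for j in topology.joints],
        "fixed_imus": list(topology.fixed_imus),
        "zupt_candidates": list(topology.zupt_candidates),
        "fixed_point_nav": [list(p) for p in topology.fixed_point_nav],
    }


def topology_from_dict(d: Mapping) -> ChainTopology:
    return ChainTopology(
        imu_ids=tuple(d["imu_ids"]),
        joints=tuple(tuple(j) for j in d.get("joints", ())),
        fixed_imus=tuple(d.get("fixed_imus", ())),
        zupt_candidates=tuple(d.get("zupt_candidates", ())),
        fixed_point_nav=tuple(tuple(p) for p in d.get("fixed_point_nav", ())),
    )


def config_to_dict(config: EstimatorConfig) -> dict:
    out: dict = {}
    for f in fields(config):
        v = getattr(config, f.name)
        if f.name in EstimatorConfig._COV_FIELDS:
            arr = np.asarray(v)
            diag = np.diag(arr)
            if np.allclose(arr, diag[0] * np.eye(3)):
                out[f.name] = float(diag[0])
            else:
                out[f.name] = [[float(x) for x in row] for row in arr]
        else:
            out[f.name] = v
    return out


def config_from_dict(d: Mapping) -> EstimatorConfig:
    known = {f.name for f in fields(EstimatorConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown estimator config keys: {sorted(unknown)}")
    return EstimatorConfig(**dict(d))
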