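"""Stream readers/writers and configuration files.

Sensor streams use SI units throughout.  Two on-disk layouts are
supported:

* CSV, long format with columns ``time, imu, sensor, x, y, z`` where
  ``sensor`` is one of ``acc`` (m/s^2), ``gyro`` (rad/s), ``mag`` (a.u.);
* HDF5 with one group per IMU id holding ``acc`` / ``gyro`` / ``mag``
  datasets of shape (T, 3) plus a shared ``/time`` dataset.

Configuration (topology + estimator settings, optionally simulation
settings) is one YAML document.  ``dataset_schema.yaml`` (shipped next to
this module) documents the adapter mapping for external HDF5 exports; it
is a schema description, not a parser.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .chain_model import (
    ChainTopology,
    EstimatorConfig,
    config_from_dict,
    config_to_dict,
    topology_from_dict,
    topology_to_dict,
)
from .measurement_models import MeasurementFrame

__all__ = [
    "write_stream",
    "read_stream",
    "write_truth",
    "read_truth",
    "write_result",
    "save_config",
    "load_config",
]

_SENSORS = ("acc", "gyro", "mag")


def _frames_to_arrays(frames: list[MeasurementFrame]):
    t = np.array([f.t for f in frames])
    acc = np.stack([f.acc for f in frames])
    gyro = np.stack([f.gyro for f in frames])
    mag = None
    if frames[0].mag is not None:
        mag = np.stack([f.mag for f in frames])
    return t, acc, gyro, mag


def write_stream(path, frames: list[MeasurementFrame], imu_ids=None) -> None:
    """Write a measurement stream (format chosen by file extension)."""
    path = Path(path)
    t, acc, gyro, mag = _frames_to_arrays(frames)
    n_imus = acc.shape[1]
    if imu_ids is None:
        imu_ids = [f"imu{i}" for i in range(n_imus)]
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("time", data=t)
            for i, name in enumerate(imu_ids):
                grp = fh.create_group(name)
                grp.create_dataset("acc", data=acc[:, i])
                grp.create_dataset("gyro", data=gyro[:, i])
                if mag is not None:
                    grp.create_dataset("mag", data=mag[:, i])
    else:
        rows = []
        for k in range(t.shape[0]):
            for i, name in enumerate(imu_ids):
                rows.append((t[k], name, "acc", *acc[k, i]))
                rows.append((t[k], name, "gyro", *gyro[k, i]))
                if mag is not None:
                    rows.append((t[k], name, "mag", *mag[k, i]))
        pd.DataFrame(rows, columns=["time", "imu", "sensor", "x", "y", "z"]).to_csv(
            path, index=False
        )


class StreamFormatError(ValueError):
    """Malformed sensor stream file."""


def _check_times(t: np.ndarray, path) -> None:
    if t.size < 2:
        raise StreamFormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        k = int(np.flatnonzero(dt <= 0)[0])
        raise StreamFormatError(f"{path}: non-monotonic time at sample {k + 1}")
    jitter = (dt.max() - dt.min()) / np.median(dt)
    if jitter > 0.01:
        raise StreamFormatError(f"{path}: sampling jitter {jitter:.1%} exceeds 1%")


def read_stream(path, imu_ids=None) -> tuple[list[MeasurementFrame], list[str]]:
    """Read a measurement stream; returns (frames, imu ids).

    Validates column completeness, time monotonicity and rate jitter
    (must stay within 1% of the median interval).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            if "time" not in fh:
                raise StreamFormatError(f"{path}: missing /time dataset")
            t = np.asarray(fh["time"])
            ids = imu_ids or sorted(k for k in fh.keys() if k != "time")
            acc, gyro, mags = [], [], []
            for name in ids:
                grp = fh[name]
                for req in ("acc", "gyro"):
                    if req not in grp:
                        raise StreamFormatError(f"{path}: IMU {name} missing '{req}'")
                acc.append(np.asarray(grp["acc"]))
                gyro.append(np.asarray(grp["gyro"]))
                mags.append(np.asarray(grp["mag"]) if "mag" in grp else None)
        acc = np.stack(acc, axis=1)
        gyro = np.stack(gyro, axis=1)
        mag = None if any(m is None for m in mags) else np.stack(mags, axis=1)
    else:
        df = pd.read_csv(path)
        required = {"time", "imu", "sensor", "x", "y", "z"}
        missing = required - set(df.columns)
        if missing:
            raise StreamFormatError(f"{path}: missing columns {sorted(missing)}")
        if df[["x", "y", "z"]].isna().any().any():
            k = int(df[["x", "y", "z"]].isna().any(axis=1).idxmax())
            raise StreamFormatError(f"{path}: incomplete 3-vector in row {k}")
        ids = imu_ids or sorted(df["imu"].unique())
        t = np.sort(df["time"].unique())
        have_mag = (df["sensor"] == "mag").any()
        acc = np.empty((t.size, len(ids), 3))
        gyro = np.empty((t.size, len(ids), 3))
        mag = np.empty((t.size, len(ids), 3)) if have_mag else None
        pivot = {}
        for sensor in _SENSORS if have_mag else _SENSORS[:2]:
            sub = df[df["sensor"] == sensor]
            for i, name in enumerate(ids):
                s = sub[sub["imu"] == name].sort_values("time")
                if s.shape[0] != t.size:
                    raise StreamFormatError(
                        f"{path}: IMU {name} sensor {sensor} has {s.shape[0]} rows, expected {t.size}"
                    )
                pivot[(sensor, i)] = s[["x", "y", "z"]].to_numpy()
        for i in range(len(ids)):
            acc[:, i] = pivot[("acc", i)]
            gyro[:, i] = pivot[("gyro", i)]
            if have_mag:
                mag[:, i] = pivot[("mag", i)]
    _check_times(np.asarray(t, dtype=float), path)
    frames = [
        MeasurementFrame(
            t=float(t[k]),
            acc=acc[k],
            gyro=gyro[k],
            mag=None if mag is None else mag[k],
        )
        for k in range(len(t))
    ]
    return frames, list(ids)


# ---------------------------------------------------------------------------
# ground truth and results (HDF5)

def write_truth(path, truth) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("time", data=truth.t)
        fh.create_dataset("rot", data=truth.rot)
        for name in ("pos", "vel", "acc", "omega", "joint_nav"):
            fh.create_dataset(name, data=getattr(truth, name))
        fh.create_dataset("joint_local_i", data=truth.joint_local_i)
        fh.create_dataset("joint_local_j", data=truth.joint_local_j)
        fh.create_dataset("segment_lengths", data=truth.segment_lengths)
        fh.attrs["rate"] = truth.rate
        fh.attrs["gravity"] = truth.gravity
        fh.attrs["mag_field"] = truth.mag_field
        fh.attrs["topology"] = yaml.safe_dump(topology_to_dict(truth.topology))
        fix = fh.create_group("fix_local")
        for l, v in truth.fix_local.items():
            fix.create_dataset(str(l), data=np.asarray(v))


def read_truth(path):
    from .simulator import GroundTruth

    with h5py.File(path, "r") as fh:
        topo = topology_from_dict(yaml.safe_load(fh.attrs["topology"]))
        fix_local = {int(k): np.asarray(v) for k, v in fh["fix_local"].items()}
        return GroundTruth(
            t=np.asarray(fh["time"]),
            rot=np.asarray(fh["rot"]),
            pos=np.asarray(fh["pos"]),
            vel=np.asarray(fh["vel"]),
            acc=np.asarray(fh["acc"]),
            omega=np.asarray(fh["omega"]),
            topology=topo,
            joint_local_i=np.asarray(fh["joint_local_i"]),
            joint_local_j=np.asarray(fh["joint_local_j"]),
            fix_local=fix_local,
            joint_nav=np.asarray(fh["joint_nav"]),
            segment_lengths=np.asarray(fh["segment_lengths"]),
            rate=float(fh.attrs["rate"]),
            gravity=float(fh.attrs["gravity"]),
            mag_field=np.asarray(fh.attrs["mag_field"]),
        )


def write_result(path, result) -> None:
    """Persist a tracking result (means, uncertainties, diagnostics)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("time", data=result.times)
        fh.create_dataset("means", data=result.means)
        fh.create_dataset("joint_uncertainty", data=result.joint_uncertainty)
        fh.create_dataset("fixed_uncertainty", data=result.fixed_uncertainty)
        fh.create_dataset("zupt_flags", data=result.zupt_flags)
        fh.create_dataset("gn_iterations", data=result.gn_iterations)
        fh.create_dataset("objective", data=result.objective)
        fh.create_dataset("final_cov", data=result.final.cov)
        fh.attrs["topology"] = yaml.safe_dump(topology_to_dict(result.topology))
        layout_doc = {str(k): [s.start, s.stop] for k, s in result.layout.blocks.items()}
        fh.attrs["layout"] = yaml.safe_dump(layout_doc)


# ---------------------------------------------------------------------------
# configuration documents

def save_config(path, topology: ChainTopology, config: EstimatorConfig, sim: dict | None = None) -> None:
    doc = {"topology": topology_to_dict(topology), "estimator": config_to_dict(config)}
    if sim:
        doc["simulation"] = sim
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> tuple[ChainTopology, EstimatorConfig, dict]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "topology" not in doc:
        raise ValueError(f"{path}: expected a mapping with a 'topology' section")
    topo = topology_from_dict(doc["topology"])
    config = config_from_dict(doc.get("estimator", {}))
    return topo, config, doc.get("simulation", {}) or {}
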