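"""Domain containers, configuration and CSV I/O for foot-mounted IMU trials.

Conventions
-----------
* World frame is right-handed, z-up; gravity vector is ``(0, 0, -gravity)``.
* Accelerometers report specific force: a stationary, level sensor reads
  approximately ``(0, 0, +gravity)`` on its own z axis.
* Quaternions are Hamilton, scalar-first (w, x, y, z), world-from-sensor.
* All sample indices are 0-based; CSV reports emit 0-based indices.
* CSV dialect: comma separator, '.' decimal, UTF-8, one header row;
  lines starting with '#' are comments and are skipped.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    ConfigurationError,
    EmptyInputError,
    FormatError,
    ValidationError,
)

__all__ = [
    "ImuRecording",
    "PipelineConfig",
    "Trajectory",
    "read_imu_csv",
    "read_quaternion_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_stride_report",
    "read_stride_report",
    "load_config",
    "REPORT_COLUMNS",
]

_FLOAT_FMT = "%.17g"

IMU_COLUMNS = ["time_s", "ax", "ay", "az", "gx", "gy", "gz"]
QUAT_COLUMNS = ["time_s", "qw", "qx", "qy", "qz"]
TRAJ_COLUMNS = ["time_s", "px", "py", "pz", "vx", "vy", "vz", "qw", "qx", "qy", "qz"]
REPORT_COLUMNS = [
    "stride_id",
    "start_idx",
    "end_idx",
    "khs_idx",
    "bx",
    "by",
    "bz",
    "dv_hs",
    "terrain",
    "direction",
    "stride_length_m",
    "height_change_m",
]


@dataclass
class ImuRecording:
    """Uniformly sampled sensor-frame accelerometer/gyroscope streams.

    Parameters
    ----------
    t : (N,) array
        Sample times in seconds, monotonically increasing.
    accel : (N, 3) array
        Specific force in m/s^2, sensor frame.
    gyro : (N, 3) array
        Angular velocity in rad/s, sensor frame.
    dt : float
        Nominal sample interval in seconds (1/128 for the sensors emulated here).
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        if self.t.size == 0:
            raise EmptyInputError("recording contains no samples")
        if not (len(self.t) == len(self.accel) == len(self.gyro)):
            raise ValidationError(
                f"length mismatch: t={len(self.t)} accel={len(self.accel)} gyro={len(self.gyro)}"
            )
        if self.accel.shape[1] != 3 or self.gyro.shape[1] != 3:
            raise ValidationError("accel and gyro must be (N, 3) arrays")
        if not self.dt > 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        if len(self.t) > 1:
            diffs = np.diff(self.t)
            if np.any(diffs <= 0):
                raise ValidationError("time stamps must be strictly increasing")
            if np.max(np.abs(diffs - self.dt)) >= 0.1 * self.dt:
                raise ValidationError(
                    "time stamps are not uniform at the declared sample interval"
                )

    @property
    def n(self) -> int:
        return len(self.t)

    def with_gyro_bias_removed(self, bias: np.ndarray) -> "ImuRecording":
        return ImuRecording(self.t, self.accel, self.gyro - np.asarray(bias, float), self.dt)


@dataclass
class PipelineConfig:
    """Tunable parameters of the reconstruction pipeline.

    Attributes
    ----------
    gravity : float
        Gravitational acceleration magnitude, m/s^2.
    ta, tw : float
        Stance (ZUPT) detection thresholds: ``| ||a|| - g | < ta`` (m/s^2) and
        ``||w|| < tw`` (rad/s) must hold simultaneously.
    central_frac : float
        Fraction of each contiguous stance period kept after trimming (the most
        stationary central portion); 0.8 keeps the central 80%.
    v_threshold_ramp, v_threshold_stair : float
        Thresholds (m/s) on the baseline-subtracted heel-strike vertical
        velocity error separating level/ramp and ramp/stair.
    b_threshold_stair : float
        Threshold (m/s^2) on the baseline-subtracted acceleration-bias
        magnitude; exceeding it marks a stair stride.
    height_boundary, forward_boundary : float
        Rectangular kinematic boundary (m) separating ramp from stair strides
        during label cleanup.
    C : float
        Correction parameter in [0, 1]: the portion of the integration
        residuals attributed to the error model (1 = full correction).
    hs_peak_threshold : float or None
        Heel-strike detector threshold on the per-sample vertical acceleration
        difference (m/s^2 per sample).  None selects an adaptive threshold:
        max(4, 6 * median |difference| over the swing).
    min_stance_dur, min_swing_dur : float
        Shortest believable stance / swing durations in seconds, used to
        smooth the raw ZUPT mask.
    """

    gravity: float = 9.80665
    ta: float = 0.4
    tw: float = 0.3
    central_frac: float = 0.8
    v_threshold_ramp: float = 0.2
    v_threshold_stair: float = 1.0
    b_threshold_stair: float = 1.2
    height_boundary: float = 0.3
    forward_boundary: float = 1.0
    C: float = 1.0
    hs_peak_threshold: Optional[float] = None
    min_stance_dur: float = 0.1
    min_swing_dur: float = 0.2

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            "gravity",
            "ta",
            "tw",
            "v_threshold_ramp",
            "v_threshold_stair",
            "b_threshold_stair",
            "height_boundary",
            "forward_boundary",
            "min_stance_dur",
            "min_swing_dur",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.hs_peak_threshold is not None and not self.hs_peak_threshold > 0:
            raise ConfigurationError(
                f"hs_peak_threshold must be positive, got {self.hs_peak_threshold}"
            )
        if not 0.0 < self.central_frac <= 1.0:
            raise ConfigurationError(f"central_frac must lie in (0, 1], got {self.central_frac}")
        if not 0.0 <= self.C <= 1.0:
            raise ConfigurationError(f"C must lie in [0, 1], got {self.C}")

    @property
    def gravity_vector(self) -> np.ndarray:
        return np.array([0.0, 0.0, -self.gravity])


@dataclass
class Trajectory:
    """Per-sample world-frame kinematic state for a stride or a whole trial."""

    t: np.ndarray
    p: np.ndarray
    v: np.ndarray
    q: Optional[np.ndarray] = None  # scalar-first unit quaternions, world-from-sensor
    stride_id: Optional[np.ndarray] = None  # -1 outside any stride

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.atleast_2d(np.asarray(self.p, dtype=float)) if np.size(self.p) else np.zeros((0, 3))
        self.v = np.atleast_2d(np.asarray(self.v, dtype=float)) if np.size(self.v) else np.zeros((0, 3))
        n = len(self.t)
        if len(self.p) != n or len(self.v) != n:
            raise ValidationError("trajectory fields must be aligned")
        if self.q is not None:
            self.q = np.atleast_2d(np.asarray(self.q, dtype=float)) if np.size(self.q) else np.zeros((0, 4))
            if len(self.q) != n:
                raise ValidationError("trajectory quaternions must be aligned")
        if self.stride_id is not None:
            self.stride_id = np.asarray(self.stride_id, dtype=int)
            if len(self.stride_id) != n:
                raise ValidationError("stride_id must be aligned")

    @property
    def n(self) -> int:
        return len(self.t)


def _read_csv(path, required, kind: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{kind} file {path} is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{kind} file {path} is missing columns: {missing}")
    return df


def read_imu_csv(path, config: Optional[PipelineConfig] = None) -> ImuRecording:
    """Read an IMU CSV (columns time_s, ax, ay, az, gx, gy, gz).

    The sample interval is estimated as the median successive time difference.
    """
    df = _read_csv(path, IMU_COLUMNS, "IMU")
    if len(df) == 0:
        raise EmptyInputError(f"IMU file {path} has a header but no rows")
    t = df["time_s"].to_numpy(dtype=float)
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0 / 128.0
    if not dt > 0:
        raise ValidationError("time stamps are not increasing")
    return ImuRecording(
        t=t,
        accel=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
        dt=dt,
    )


def read_quaternion_csv(path) -> np.ndarray:
    """Read an externally estimated orientation stream; returns (N, 4) wxyz."""
    df = _read_csv(path, QUAT_COLUMNS, "quaternion")
    if len(df) == 0:
        raise EmptyInputError(f"quaternion file {path} has a header but no rows")
    q = df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
    norms = np.linalg.norm(q, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValidationError("quaternions must be unit norm")
    return q / norms[:, None]


def write_trajectory_csv(trajectory: Trajectory, path) -> None:
    q = trajectory.q
    if q is None:
        q = np.tile([1.0, 0.0, 0.0, 0.0], (trajectory.n, 1))
    df = pd.DataFrame(
        np.column_stack([trajectory.t, trajectory.p, trajectory.v, q]) if trajectory.n else
        np.zeros((0, 11)),
        columns=TRAJ_COLUMNS,
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# world frame, z-up; quaternions scalar-first world-from-sensor\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_trajectory_csv(path) -> Trajectory:
    df = _read_csv(path, TRAJ_COLUMNS, "trajectory")
    return Trajectory(
        t=df["time_s"].to_numpy(float),
        p=df[["px", "py", "pz"]].to_numpy(float),
        v=df[["vx", "vy", "vz"]].to_numpy(float),
        q=df[["qw", "qx", "qy", "qz"]].to_numpy(float) if len(df) else np.zeros((0, 4)),
    )


def write_stride_report(strides: Sequence, solutions: Sequence, labels: Sequence,
                        path, geometry: Optional[Sequence] = None) -> None:
    """Write one CSV row per stride.

    Parameters
    ----------
    strides : sequence of StrideSegment
    solutions : sequence of ErrorSolution
    labels : sequence of TerrainLabel
    geometry : optional sequence of (stride_length_m, height_change_m)
    """
    if not (len(strides) == len(solutions) == len(labels)):
        raise ValidationError("strides, solutions and labels must have equal length")
    if geometry is not None and len(geometry) != len(strides):
        raise ValidationError("geometry must align with strides")
    rows = []
    for i, (seg, sol, lab) in enumerate(zip(strides, solutions, labels)):
        length, dh = (geometry[i] if geometry is not None else (np.nan, np.nan))
        rows.append(
            dict(
                stride_id=i,
                start_idx=seg.start_idx,
                end_idx=seg.end_idx,
                khs_idx=-1 if seg.khs_idx is None else int(seg.khs_idx),
                bx=sol.b[0],
                by=sol.b[1],
                bz=sol.b[2],
                dv_hs=sol.dv_hs,
                terrain=lab.terrain.name,
                direction=int(lab.direction),
                stride_length_m=length,
                height_change_m=dh,
            )
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# indices are 0-based; khs_idx -1 means no heel strike detected\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_stride_report(path) -> pd.DataFrame:
    return _read_csv(path, REPORT_COLUMNS, "stride report")


def load_config(path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML or JSON file mirroring the field names."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) if not text.lstrip().startswith("{") else json.loads(text)
    if data is None:
        data = {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    return PipelineConfig(**data)
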