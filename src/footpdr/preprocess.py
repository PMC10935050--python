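"""Orientation estimation, ZUPT detection and stride segmentation.

The preprocessing chain for one trial is

1. estimate the static gyroscope bias over an initial stationary window and
   subtract it,
2. strapdown-integrate the gyroscope into a world-from-sensor quaternion
   series, with a tilt-only gravity correction distributed over every stance
   (foot-flat) period,
3. rotate the measured specific force into the world frame and add gravity,
4. detect stance samples (ZUPT mask), smooth the mask and trim each stance
   run to its most stationary central portion,
5. cut the trial into strides between consecutive stance runs and locate the
   heel-strike impact inside each swing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from ._quat import (
    align_to_z,
    enforce_sign_continuity,
    quat_multiply,
    quat_to_rotation,
    rotation_to_quat,
    rotvec_quat,
)
from .exceptions import CalibrationError, ValidationError
from .io_gait import ImuRecording, PipelineConfig

__all__ = [
    "OrientationSeries",
    "StrideSegment",
    "estimate_gyro_bias",
    "estimate_orientation",
    "world_accel",
    "detect_zupt",
    "refine_zupt",
    "segment_strides",
    "detect_heel_strike",
    "true_runs",
]


@dataclass
class OrientationSeries:
    """Per-sample world-from-sensor unit quaternions (scalar-first)."""

    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        norms = np.linalg.norm(self.q, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValidationError("orientation quaternions must be unit norm")
        self.q = self.q / norms[:, None]
        enforce_sign_continuity(self.q)

    def __len__(self) -> int:
        return len(self.q)

    @property
    def rotations(self) -> Rotation:
        return quat_to_rotation(self.q)

    def matrices(self) -> np.ndarray:
        return self.rotations.as_matrix()


@dataclass
class StrideSegment:
    """Half-open sample range [start_idx, end_idx) of one stride.

    ``zupt_mask`` is the full-trial refined stance mask (shared, not sliced);
    ``khs_idx`` is the trial-global heel-strike sample, strictly inside the
    stride when present.
    """

    start_idx: int
    end_idx: int
    zupt_mask: np.ndarray
    khs_idx: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.start_idx < self.end_idx:
            raise ValidationError("stride must satisfy start < end")
        if self.khs_idx is not None and not self.start_idx < self.khs_idx < self.end_idx:
            raise ValidationError("heel strike must lie strictly inside the stride")

    @property
    def N(self) -> int:
        return self.end_idx - self.start_idx

    @property
    def slice(self) -> slice:
        return slice(self.start_idx, self.end_idx)

    def mask_slice(self) -> np.ndarray:
        return self.zupt_mask[self.start_idx : self.end_idx]


def true_runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open [start, end) ranges of consecutive True samples."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    padded = np.concatenate([[False], m, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def estimate_gyro_bias(
    recording: ImuRecording,
    stationary_window: Tuple[int, int],
    config: Optional[PipelineConfig] = None,
) -> np.ndarray:
    """Mean gyroscope reading over a long stationary window.

    The static gyro bias is the dominant, easily removed component of the
    gyroscope error; the caller subtracts the returned vector from every
    sample.  The window must span at least one second and pass the stance
    condition at every sample.
    """
    cfg = config or PipelineConfig()
    a, b = stationary_window
    if not 0 <= a < b <= recording.n:
        raise CalibrationError(f"window [{a}, {b}) out of range")
    if (b - a) * recording.dt < 1.0:
        raise CalibrationError("stationary window must span at least 1 s")
    sub = ImuRecording(recording.t[a:b], recording.accel[a:b], recording.gyro[a:b], recording.dt)
    if not np.all(detect_zupt(sub, cfg.ta, cfg.tw, cfg.gravity)):
        raise CalibrationError("window is not stationary under the ZUPT condition")
    return recording.gyro[a:b].mean(axis=0)


def estimate_orientation(
    recording: ImuRecording,
    zupt_mask: np.ndarray,
    q0: np.ndarray,
    gravity: float = 9.80665,
) -> OrientationSeries:
    """Strapdown quaternion integration with stance-phase gravity correction.

    The gyroscope (bias already removed) is integrated sample by sample,
    q(k) = q(k-1) * q(w(k) dt).  Over every contiguous stance run of
    ``zupt_mask`` the mean measured specific force, rotated into the world
    frame, is compared with +z: the tilt-only rotation aligning the two is
    blended in by spherical interpolation across the run, so the estimate
    never jumps.  Heading is deliberately left uncorrected.
    """
    q0 = np.asarray(q0, dtype=float)
    if abs(np.linalg.norm(q0) - 1.0) > 1e-6:
        raise ValidationError("initial quaternion must be unit norm")
    n = recording.n
    dt = recording.dt
    q_raw = np.empty((n, 4))
    q_raw[0] = q0 / np.linalg.norm(q0)
    q = q_raw[0]
    gyro = recording.gyro
    for k in range(1, n):
        q = quat_multiply(q, rotvec_quat(gyro[k] * dt))
        q = q / np.linalg.norm(q)
        q_raw[k] = q

    rot_raw = quat_to_rotation(q_raw)
    out = np.empty((n, 4))
    correction = Rotation.identity()
    cursor = 0
    for a, b in true_runs(np.asarray(zupt_mask, dtype=bool)):
        if a > cursor:
            seg = correction * rot_raw[cursor:a]
            out[cursor:a] = rotation_to_quat(seg)
        seg = correction * rot_raw[a:b]
        f_world = seg.apply(recording.accel[a:b]).mean(axis=0)
        tilt = align_to_z(f_world)
        rv = tilt.as_rotvec()
        fracs = np.arange(1, b - a + 1) / (b - a)
        blended = Rotation.from_rotvec(np.outer(fracs, rv)) * seg
        out[a:b] = rotation_to_quat(blended)
        correction = tilt * correction
        cursor = b
    if cursor < n:
        out[cursor:] = rotation_to_quat(correction * rot_raw[cursor:])
    return OrientationSeries(out)


def world_accel(
    recording: ImuRecording,
    orientation: OrientationSeries,
    b: Optional[np.ndarray] = None,
    gravity: float = 9.80665,
) -> np.ndarray:
    """World-frame linear acceleration a_w(k) = R(k) (a_m(k) - b) + g.

    With a perfect orientation and bias estimate this is zero whenever the
    sensor is at rest (gravity cancellation).
    """
    if len(orientation) != recording.n:
        raise ValidationError("orientation and recording must be aligned")
    a = recording.accel if b is None else recording.accel - np.asarray(b, float)
    g_vec = np.array([0.0, 0.0, -gravity])
    return orientation.rotations.apply(a) + g_vec


def detect_zupt(recording: ImuRecording, ta: float, tw: float, gravity: float = 9.80665) -> np.ndarray:
    """Raw stance mask: | ||a_m|| - g | < ta AND ||w|| < tw, per sample."""
    if not (ta > 0 and tw > 0):
        raise ValidationError("ZUPT thresholds must be positive")
    a_norm = np.linalg.norm(recording.accel, axis=1)
    w_norm = np.linalg.norm(recording.gyro, axis=1)
    return (np.abs(a_norm - gravity) < ta) & (w_norm < tw)


def refine_zupt(
    mask: np.ndarray,
    dt: float,
    min_stance_dur: float = 0.1,
    min_swing_dur: float = 0.2,
    central_frac: float = 0.8,
) -> np.ndarray:
    """Smooth the raw stance mask and trim each run to its central portion.

    Stages: (1) stance runs shorter than ``min_stance_dur`` are removed,
    (2) interior swing gaps shorter than ``min_swing_dur`` are filled,
    (3) every surviving stance run of length L is reduced to its central
    round(central_frac * L) samples, with the extra sample trimmed from the
    run's end when the trim is odd.
    """
    if not 0.0 < central_frac <= 1.0:
        raise ValidationError("central_frac must lie in (0, 1]")
    m = np.asarray(mask, dtype=bool).copy()
    for a, b in true_runs(m):
        if (b - a) * dt < min_stance_dur:
            m[a:b] = False
    # fill short interior swing gaps (gaps touching the trial edges are kept)
    gaps = true_runs(~m)
    for a, b in gaps:
        if a == 0 or b == len(m):
            continue
        if (b - a) * dt < min_swing_dur:
            m[a:b] = True
    if central_frac < 1.0:
        for a, b in true_runs(m):
            length = b - a
            keep = max(1, int(np.floor(central_frac * length + 0.5)))
            drop = length - keep
            front = drop // 2
            back = drop - front
            m[a : a + front] = False
            m[b - back : b] = False
    return m


def segment_strides(refined_mask: np.ndarray) -> List[StrideSegment]:
    """One stride per consecutive pair of stance runs.

    The stride starts at the midpoint sample of one stance run and ends at the
    midpoint of the next (half-open range), so each stride is bounded by
    foot-flat samples on both sides.  Fewer than two runs yields no strides.
    """
    mask = np.asarray(refined_mask, dtype=bool)
    runs = true_runs(mask)
    if len(runs) < 2:
        return []
    mids = [a + (b - a) // 2 for a, b in runs]
    return [
        StrideSegment(start_idx=mids[i], end_idx=mids[i + 1], zupt_mask=mask)
        for i in range(len(mids) - 1)
    ]


def detect_heel_strike(
    world_accel_z: np.ndarray,
    stride: StrideSegment,
    hs_peak_threshold: Optional[float] = None,
) -> Optional[int]:
    """First high peak in the vertical acceleration difference inside the swing.

    Computes d(k) = a_w,z(k) - a_w,z(k-1) over the stride and returns the
    trial-global index of the first local maximum of |d| that exceeds the
    threshold, restricted to swing samples (stance excluded).  The magnitude
    is used because a bandwidth-limited impact appears as a glitch of either
    sign.  With no threshold given, an adaptive one is used:
    max(4 m/s^2, 6 * median |d| over the swing).  Returns None when no peak
    qualifies — a valid outcome, not an error.
    """
    if stride.N < 4:
        raise ValidationError("stride too short for heel-strike detection")
    z = np.asarray(world_accel_z, dtype=float)[stride.slice]
    swing = ~stride.mask_slice()
    d = np.empty_like(z)
    d[0] = 0.0
    d[1:] = np.diff(z)
    ad = np.abs(d)
    candidates = np.flatnonzero(swing)
    candidates = candidates[candidates >= 1]
    if candidates.size == 0:
        return None
    if hs_peak_threshold is None:
        hs_peak_threshold = max(4.0, 6.0 * float(np.median(ad[candidates])))
    n = len(ad)
    for k in candidates:
        if ad[k] <= hs_peak_threshold:
            continue
        left = ad[k - 1] if k - 1 >= 0 else -np.inf
        right = ad[k + 1] if k + 1 < n else -np.inf
        if ad[k] >= left and ad[k] >= right:
            return stride.start_idx + int(k)
    return None
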