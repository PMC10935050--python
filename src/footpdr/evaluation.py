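"""Baselines, evaluation metrics and impact diagnostics.

The comparison baseline is the traditional linear ZUPT de-drift: the residual
velocity is modelled as a ramp growing linearly with time since the previous
stance and subtracted, optionally followed by a constant vertical-velocity
offset that zeroes the height change.  Unlike the impact-aware model, this
attributes the heel-strike velocity discontinuity to a smooth drift, which
distorts the swing-phase height profile and leaves an end-height error
whenever the impulse dominates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import periodogram

from .error_model import _subrange
from .exceptions import EvaluationError, MetricError, ValidationError
from .io_gait import ImuRecording, Trajectory
from .preprocess import StrideSegment
from .terrain import Terrain, TerrainLabel

__all__ = [
    "TerrainSegmentTruth",
    "zupt_linear_dedrift",
    "height_error_by_terrain",
    "impact_metrics",
    "confusion_matrix",
    "ConfusionResult",
]


@dataclass(frozen=True)
class TerrainSegmentTruth:
    """Ground truth for one contiguous terrain segment of a route."""

    label: TerrainLabel
    reference_height_change: float  # m, signed; 0 for level ground

    def __post_init__(self) -> None:
        if self.label.terrain is Terrain.LEVEL and self.reference_height_change != 0.0:
            raise ValidationError("level segments have zero reference height change")


def zupt_linear_dedrift(
    world_accel: np.ndarray,
    stride: Optional[StrideSegment],
    dt: float,
    zupt_mask: Optional[np.ndarray] = None,
    dedrift_height: bool = False,
) -> Trajectory:
    """Linear ZUPT de-drift baseline for one stride.

    Raw integration over the stride's sub-range, then subtraction of the
    linear ramp (k/N) * v_residual from the velocity, and re-integration of
    the position from the corrected velocity (trapezoidal, consistent with
    the forward recursion).  With ``dedrift_height`` the constant vertical
    velocity offset h/(N dt) is additionally removed before re-integration,
    zeroing (almost all of) the height change as well.

    End velocity is exactly zero by construction, whatever the input.
    """
    a = np.atleast_2d(np.asarray(world_accel, dtype=float))
    if stride is not None:
        a = a[stride.slice]
        if zupt_mask is None:
            zupt_mask = stride.mask_slice()
    n = len(a)
    t = np.arange(n) * dt
    s, e = _subrange(zupt_mask, n)
    p = np.zeros((n, 3))
    v = np.zeros((n, 3))
    if e - s == 0:
        return Trajectory(t=t, p=p, v=v)
    v_sub = np.cumsum(a[s:e], axis=0) * dt
    m = e - s
    ramp = np.arange(1, m + 1)[:, None] / m
    v_corr = v_sub - ramp * v_sub[-1]

    def reintegrate(vel: np.ndarray) -> np.ndarray:
        v_prev = np.vstack([np.zeros(3), vel[:-1]])
        return np.cumsum(0.5 * (vel + v_prev) * dt, axis=0)

    p_sub = reintegrate(v_corr)
    if dedrift_height:
        v_corr = v_corr.copy()
        v_corr[:, 2] -= p_sub[-1, 2] / (m * dt)
        p_sub = reintegrate(v_corr)
    v[s:e] = v_corr
    p[s:e] = p_sub
    p[e:] = p_sub[-1]
    return Trajectory(t=t, p=p, v=v)


def _stride_ranges(trajectory: Trajectory) -> List[Tuple[int, int]]:
    sid = trajectory.stride_id
    if sid is None:
        raise EvaluationError("trajectory carries no stride ids")
    ranges = []
    for j in range(sid.max() + 1):
        idx = np.flatnonzero(sid == j)
        if idx.size == 0:
            raise EvaluationError(f"stride {j} missing from trajectory")
        ranges.append((int(idx[0]), int(idx[-1]) + 1))
    return ranges


def height_error_by_terrain(
    trajectory: Trajectory,
    labels: Sequence[TerrainLabel],
    truth: Sequence[TerrainSegmentTruth],
) -> Dict[Terrain, Dict[str, float]]:
    """Height error at the beginning and end of each terrain segment.

    Contiguous runs of same-labelled strides form segments that must align
    one-to-one with the truth list.  Each segment's error is
    |reconstructed height change - reference|; per terrain class the totals
    and the mean error per stride (total / number of strides) are returned.
    """
    ranges = _stride_ranges(trajectory)
    if len(ranges) != len(labels):
        raise EvaluationError("labels must align with the trajectory's strides")
    segments: List[Tuple[TerrainLabel, int, int]] = []  # label, first stride, last stride
    for j, lab in enumerate(labels):
        if segments and segments[-1][0] == lab:
            segments[-1] = (lab, segments[-1][1], j)
        else:
            segments.append((lab, j, j))
    if len(segments) != len(truth):
        raise EvaluationError(
            f"found {len(segments)} label segments but {len(truth)} truth segments"
        )
    stats: Dict[Terrain, Dict[str, float]] = {
        terr: {"total_error": 0.0, "n_strides": 0, "n_segments": 0} for terr in Terrain
    }
    for (lab, j0, j1), ref in zip(segments, truth):
        start = ranges[j0][0]
        end = ranges[j1][1]
        dh = float(trajectory.p[end - 1, 2] - trajectory.p[start, 2])
        err = abs(dh - ref.reference_height_change)
        entry = stats[ref.label.terrain]
        entry["total_error"] += err
        entry["n_strides"] += j1 - j0 + 1
        entry["n_segments"] += 1
    for entry in stats.values():
        entry["mean_error_per_stride"] = (
            entry["total_error"] / entry["n_strides"] if entry["n_strides"] else 0.0
        )
    return stats


def impact_metrics(recording: ImuRecording, stride: StrideSegment) -> Tuple[float, float]:
    """Heel-strike impact diagnostics for one stride.

    Returns the peak acceleration magnitude (m/s^2) over the stride and the
    fraction of the mean-removed acceleration-magnitude signal energy in the
    40-64 Hz band (rectangular-window periodogram over the full stride,
    band edges inclusive, normalised by the total energy above 0 Hz).
    """
    if stride.N < 16:
        raise MetricError("stride too short for impact metrics (need >= 16 samples)")
    mag = np.linalg.norm(recording.accel[stride.slice], axis=1)
    peak = float(mag.max())
    f, psd = periodogram(mag - mag.mean(), fs=1.0 / recording.dt, window="boxcar", detrend=False)
    total = psd[f > 0].sum()
    if total <= 0:
        return peak, 0.0
    band = psd[(f >= 40.0) & (f <= 64.0)].sum()
    return peak, float(band / total)


@dataclass
class ConfusionResult:
    counts: np.ndarray  # rows = true, cols = predicted, order LEVEL/RAMP/STAIR
    per_class_accuracy: Dict[Terrain, float]
    overall_accuracy: float
    order: Tuple[Terrain, ...] = (Terrain.LEVEL, Terrain.RAMP, Terrain.STAIR)


def confusion_matrix(
    predicted: Sequence[TerrainLabel],
    true: Sequence[TerrainLabel],
) -> ConfusionResult:
    """3x3 terrain confusion counts with per-class and overall accuracy."""
    if len(predicted) != len(true):
        raise ValidationError("predicted and true label lists must align")
    order = (Terrain.LEVEL, Terrain.RAMP, Terrain.STAIR)
    index = {terr: i for i, terr in enumerate(order)}
    counts = np.zeros((3, 3), dtype=int)
    for p_lab, t_lab in zip(predicted, true):
        counts[index[t_lab.terrain], index[p_lab.terrain]] += 1
    row_sums = counts.sum(axis=1)
    per_class = {
        terr: (counts[i, i] / row_sums[i] if row_sums[i] else np.nan)
        for i, terr in enumerate(order)
    }
    total = counts.sum()
    overall = float(np.trace(counts) / total) if total else np.nan
    return ConfusionResult(counts=counts, per_class_accuracy=per_class, overall_accuracy=overall)
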