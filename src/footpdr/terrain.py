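"""Stride-wise terrain determination (level / ramp / stair, ascent / descent).

Every stride — whatever the true terrain — is first solved with the *full*
error model, i.e. under the level-ground zero-height assumption.  On level
ground both the heel-strike velocity error and the bias magnitude sit in a
stable band; on a ramp or a staircase the solver must invent a large impulse
(and bias) to explain away the real height change, so the solution vector
deviates sharply from the trial baseline.  Thresholding the deviations
classifies the terrain, and the sign of the baseline-subtracted impulse gives
the ascent/descent direction.  A geometry check (rectangular forward-distance
/ height-change boundary) and a consecutiveness check clean up residual
ramp/stair confusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum, IntEnum
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .error_model import ErrorSolution
from .exceptions import ConfigurationError, ValidationError
from .io_gait import PipelineConfig
from .preprocess import StrideSegment

__all__ = [
    "Terrain",
    "Direction",
    "TerrainLabel",
    "baseline_iqm",
    "classify_strides",
    "assign_default_khs",
    "cleanup_labels",
]


class Terrain(Enum):
    LEVEL = "LEVEL"
    RAMP = "RAMP"
    STAIR = "STAIR"


class Direction(IntEnum):
    DESCENT = -1
    NONE = 0
    ASCENT = 1


@dataclass(frozen=True)
class TerrainLabel:
    terrain: Terrain
    direction: Direction = Direction.NONE

    def __post_init__(self) -> None:
        if self.terrain is Terrain.LEVEL and self.direction is not Direction.NONE:
            raise ValidationError("level strides carry no direction")
        if self.terrain is not Terrain.LEVEL and self.direction is Direction.NONE:
            raise ValidationError("ramp/stair strides need an ascent/descent direction")

    @classmethod
    def level(cls) -> "TerrainLabel":
        return cls(Terrain.LEVEL, Direction.NONE)

    @classmethod
    def ramp(cls, ascending: bool = True) -> "TerrainLabel":
        return cls(Terrain.RAMP, Direction.ASCENT if ascending else Direction.DESCENT)

    @classmethod
    def stair(cls, ascending: bool = True) -> "TerrainLabel":
        return cls(Terrain.STAIR, Direction.ASCENT if ascending else Direction.DESCENT)


def baseline_iqm(values: Sequence[float]) -> float:
    """Mean of the 2nd and 3rd quartiles (interquartile mean).

    Sorts the values and averages the elements with rank in [n/4, 3n/4)
    (floor-based).  This is the baseline that removes the level-ground offset
    from the solution vectors; with fewer than 4 values it falls back to the
    plain median (with a warning).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValidationError("baseline requires at least one value")
    if n < 4:
        warnings.warn("fewer than 4 values: interquartile mean falls back to median", stacklevel=2)
        return float(np.median(v))
    return float(v[n // 4 : (3 * n) // 4].mean())


def classify_strides(
    solutions: Sequence[ErrorSolution],
    config: Optional[PipelineConfig] = None,
) -> List[TerrainLabel]:
    """Threshold the full-model solution vectors against the trial baseline.

    dv_dev(j) = dv_hs(j) - IQM(dv_hs);  b_dev(j) = | ||b(j)|| - IQM(||b||) |.
    STAIR when b_dev > b_threshold_stair or |dv_dev| > v_threshold_stair
    (checked last, so it overrides the ramp decision); otherwise RAMP when
    |dv_dev| > v_threshold_ramp; otherwise LEVEL.  Direction is the sign of
    dv_dev for non-level strides.
    """
    cfg = config or PipelineConfig()
    dv = np.array([s.dv_hs for s in solutions], dtype=float)
    b_mag = np.array([np.linalg.norm(s.b) for s in solutions], dtype=float)
    dv_dev = dv - baseline_iqm(dv)
    b_dev = np.abs(b_mag - baseline_iqm(b_mag))
    labels: List[TerrainLabel] = []
    for j in range(len(solutions)):
        is_stair = b_dev[j] > cfg.b_threshold_stair or abs(dv_dev[j]) > cfg.v_threshold_stair
        is_ramp = abs(dv_dev[j]) > cfg.v_threshold_ramp
        if is_stair or is_ramp:
            direction = Direction.ASCENT if dv_dev[j] > 0 else Direction.DESCENT
            labels.append(TerrainLabel(Terrain.STAIR if is_stair else Terrain.RAMP, direction))
        else:
            labels.append(TerrainLabel.level())
    return labels


def assign_default_khs(strides: Sequence[StrideSegment]) -> List[StrideSegment]:
    """Give strides without a detected heel strike the average timing.

    The mean stride-relative fraction (khs - start)/N of the strides with a
    detection is applied to each stride lacking one.  The assigned index is
    used for terrain determination only, never for trajectory reconstruction.
    """
    fracs = [
        (s.khs_idx - s.start_idx) / s.N for s in strides if s.khs_idx is not None
    ]
    if not fracs:
        raise ConfigurationError("no stride has a detected heel strike")
    mean_frac = float(np.mean(fracs))
    out: List[StrideSegment] = []
    for s in strides:
        if s.khs_idx is not None:
            out.append(s)
        else:
            khs = s.start_idx + int(round(mean_frac * s.N))
            khs = min(max(khs, s.start_idx + 1), s.end_idx - 1)
            out.append(replace(s, khs_idx=khs))
    return out


def _flip_by_geometry(
    label: TerrainLabel,
    forward: float,
    height: float,
    cfg: PipelineConfig,
) -> TerrainLabel:
    """Rectangular kinematic boundary: ramps show larger forward distance and
    smaller height change than stairs.  A label is flipped only when *both*
    indicators contradict it, so strides near the boundary keep the
    solution-vector decision."""
    ramp_like = forward > cfg.forward_boundary and abs(height) < cfg.height_boundary
    stair_like = forward <= cfg.forward_boundary and abs(height) >= cfg.height_boundary
    if label.terrain is Terrain.STAIR and ramp_like:
        return TerrainLabel(Terrain.RAMP, label.direction)
    if label.terrain is Terrain.RAMP and stair_like:
        return TerrainLabel(Terrain.STAIR, label.direction)
    return label


def cleanup_labels(
    labels: Sequence[TerrainLabel],
    stride_geometry: Sequence[Tuple[float, float]],
    config: Optional[PipelineConfig] = None,
) -> List[TerrainLabel]:
    """Clean wrong determinations with geometry and consecutiveness.

    (a) every non-level stride is checked against the rectangular
    forward-distance / height-change boundary (see :func:`_flip_by_geometry`);
    (b) isolated single strides flanked on both sides by one common label
    (same direction for ramps/stairs) adopt the flanking label.  The two rules
    are iterated to a fixpoint, making the operation idempotent.

    ``stride_geometry`` holds per-stride (forward_distance, height_change)
    from the raw (uncorrected) integration — nothing is re-integrated.
    """
    cfg = config or PipelineConfig()
    if len(labels) != len(stride_geometry):
        raise ValidationError("labels and geometry must align")
    current = list(labels)
    for _ in range(len(current) + 1):
        updated = [
            _flip_by_geometry(lab, fwd, dh, cfg) if lab.terrain is not Terrain.LEVEL else lab
            for lab, (fwd, dh) in zip(current, stride_geometry)
        ]
        for j in range(1, len(updated) - 1):
            left, mid, right = updated[j - 1], updated[j], updated[j + 1]
            if left == right and mid != left:
                updated[j] = left
        if updated == current:
            break
        current = updated
    return current
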