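"""Per-runner pacing metrics.

For runner *i* on a course with segments ``d_j`` (metres) and segment times
``t_ij`` (seconds):

* average race speed  ``v̄_i = D / T_i``  (total distance over finish time),
* checkpoint speed    ``v_ij = d_j / t_ij``,
* change in checkpoint speed  ``CCS_ij = 100 (v_ij - v̄_i) / v̄_i``  (%),
* average change in checkpoint speed  ``ACCS_i = mean_j |CCS_ij|``  (%).

Signed CCS is kept for description and plotting; the absolute values feed
the inferential battery (mixing signs would cancel and understate pacing
variability).  ACCS is a scalar per-runner pacing-variability index: 0 for a
perfectly even pacer, larger the more the runner deviates from their own
mean speed.

``classify_shape`` turns a speed profile into one of the verbal pacing
archetypes (even / positive / negative / reverse-J / parabolic), using a
tolerance band, default 2 % of the profile mean, inside which speeds count
as equal.  A reverse-J profile slows to a late minimum and speeds up again
at the end without exceeding the early pace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .course import CourseDefinition
from .records import Cohort, RunnerRecord, segment_times

__all__ = [
    "PacingProfile",
    "PacingShape",
    "accs",
    "average_speed",
    "ccs",
    "checkpoint_speeds",
    "classify_shape",
    "cohort_metrics",
    "compute_profile",
]

SHAPE_LABELS = ("even", "positive", "negative", "reverse_j", "parabolic", "other")


@dataclass(frozen=True)
class PacingShape:
    label: str
    minimum_checkpoint: int  # 1-based argmin of speed (first occurrence)
    end_spurt: bool


@dataclass(frozen=True)
class PacingProfile:
    """All pacing quantities for one runner."""

    runner_id: str
    checkpoint_speeds: np.ndarray  # m/s
    average_speed: float  # m/s
    ccs_signed: np.ndarray  # %
    ccs_abs: np.ndarray  # %
    accs: float  # %


def average_speed(record: RunnerRecord, course: CourseDefinition) -> float:
    """Average race speed D/T in m/s."""
    return course.total_m / record.cumulative_s[-1]


def checkpoint_speeds(record: RunnerRecord, course: CourseDefinition) -> np.ndarray:
    """Per-segment speeds d_j/t_j in m/s."""
    return course.segment_m_array / segment_times(record)


def ccs(
    checkpoint_speeds: np.ndarray | list[float], average_speed: float
) -> tuple[np.ndarray, np.ndarray]:
    """Signed and absolute percentage change of checkpoint speed vs average.

    Returns ``(signed, absolute)``; signed for plots, absolute for statistics.
    """
    if not average_speed > 0:
        raise ValueError(f"average speed must be positive, got {average_speed}")
    v = np.asarray(checkpoint_speeds, dtype=float)
    signed = 100.0 * (v - average_speed) / average_speed
    return signed, np.abs(signed)


def accs(ccs_abs: np.ndarray | list[float]) -> float:
    """Mean of the absolute CCS values (%); the scalar pacing index."""
    arr = np.asarray(ccs_abs, dtype=float)
    if arr.size == 0:
        raise ValueError("ACCS of an empty CCS list is undefined")
    return float(arr.mean())


def compute_profile(record: RunnerRecord, course: CourseDefinition) -> PacingProfile:
    v = checkpoint_speeds(record, course)
    vbar = average_speed(record, course)
    signed, absolute = ccs(v, vbar)
    return PacingProfile(
        runner_id=record.runner_id,
        checkpoint_speeds=v,
        average_speed=vbar,
        ccs_signed=signed,
        ccs_abs=absolute,
        accs=accs(absolute),
    )


def _non_increasing(v: np.ndarray, band: float) -> bool:
    return bool(np.all(v[1:] <= v[:-1] + band))


def _non_decreasing(v: np.ndarray, band: float) -> bool:
    return bool(np.all(v[1:] >= v[:-1] - band))


def classify_shape(
    checkpoint_speeds: np.ndarray | list[float], tolerance: float = 2.0
) -> PacingShape:
    """Classify a speed profile into a pacing archetype.

    ``tolerance`` is the equality band in percent of the profile mean speed.
    Checks are applied in order: even, positive, negative, reverse_j,
    parabolic, other.  A reverse-J requires the (first) global minimum at
    checkpoint ``k* >= ceil(N/2)`` but before the last, a non-increasing
    approach to it, and a final speed more than one band above the minimum
    yet not above the starting speed (an end rise past the start is the
    parabolic fast-slow-fast shape instead).
    """
    v = np.asarray(checkpoint_speeds, dtype=float)
    if v.size < 3:
        raise ValueError(f"need at least 3 checkpoints, got {v.size}")
    if tolerance < 0:
        raise ValueError(f"tolerance must be non-negative, got {tolerance}")
    mean = float(v.mean())
    band = tolerance / 100.0 * mean
    k = int(np.argmin(v))  # first occurrence
    minimum_checkpoint = k + 1
    end_spurt = bool(v[-1] > v[-2] + band)

    n = v.size
    if np.all(np.abs(v - mean) <= band):
        label = "even"
    elif _non_increasing(v, band):
        label = "positive"
    elif _non_decreasing(v, band):
        label = "negative"
    elif (
        minimum_checkpoint >= math.ceil(n / 2)
        and minimum_checkpoint < n
        and v[-1] > v[k] + band
        and v[-1] <= v[0] + band
        and _non_increasing(v[: k + 1], band)
    ):
        label = "reverse_j"
    elif (
        0 < k < n - 1
        and _non_increasing(v[: k + 1], band)
        and _non_decreasing(v[k:], band)
        and v[-1] > v[0] + band
    ):
        label = "parabolic"
    else:
        label = "other"
    return PacingShape(
        label=label, minimum_checkpoint=minimum_checkpoint, end_spurt=end_spurt
    )


def cohort_metrics(cohort: Cohort, tolerance: float = 2.0) -> pd.DataFrame:
    """Metrics table: one row per runner.

    Columns: runner_id, sex, age, average_speed_ms, cp{j}_speed,
    cp{j}_ccs_signed, accs, shape_label, minimum_checkpoint, end_spurt.
    """
    course = cohort.course
    n_cp = course.n_checkpoints
    cum = cohort.cumulative_matrix()
    seg = np.diff(cum, prepend=0, axis=1).astype(float)
    speeds = course.segment_m_array / seg
    vbar = course.total_m / cum[:, -1].astype(float)
    signed = 100.0 * (speeds - vbar[:, None]) / vbar[:, None]
    accs_vec = np.abs(signed).mean(axis=1)

    shapes = [classify_shape(row, tolerance) for row in speeds]
    data: dict[str, object] = {
        "runner_id": [r.runner_id for r in cohort.records],
        "sex": cohort.sexes(),
        "age": cohort.ages(),
        "average_speed_ms": vbar,
    }
    for j in range(n_cp):
        data[f"cp{j + 1}_speed"] = speeds[:, j]
    for j in range(n_cp):
        data[f"cp{j + 1}_ccs_signed"] = signed[:, j]
    data["accs"] = accs_vec
    data["shape_label"] = [s.label for s in shapes]
    data["minimum_checkpoint"] = [s.minimum_checkpoint for s in shapes]
    data["end_spurt"] = [s.end_spurt for s in shapes]
    return pd.DataFrame(data)
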