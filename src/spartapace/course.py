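"""Checkpointed course model.

A course is an ordered sequence of timed segments ("checkpoints" in race
parlance): segment ``j`` has a length ``d_j`` and the cumulative distance at
checkpoint ``j`` is ``sum(d_1..d_j)``.  Distances are stored in km (as race
organisers publish them) and exposed in metres for all speed arithmetic.
Checkpoint indices are 1-based, matching published results lists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "CheckpointSegment",
    "CourseDefinition",
    "CourseFormatError",
    "CourseValidationError",
    "course_from_segments",
    "load_course",
    "spartathlon_course",
]

#: relative tolerance for the declared-total vs segment-sum check
_REL_TOL = 1e-9


class CourseFormatError(ValueError):
    """A course file could not be parsed against the schema."""


class CourseValidationError(ValueError):
    """A parsed course violates a geometric invariant."""


@dataclass(frozen=True)
class CheckpointSegment:
    """One timed segment of the course (1-based ``index`` along the route)."""

    index: int
    label: str
    segment_km: float
    cumulative_km: float

    @property
    def segment_m(self) -> float:
        return self.segment_km * 1000.0

    @property
    def cumulative_m(self) -> float:
        return self.cumulative_km * 1000.0


@dataclass(frozen=True)
class CourseDefinition:
    """An ordered, validated set of checkpoint segments.

    The time limit is a property of the course, not a global constant, so
    that races other than the 36 h Athens-Sparta event can be modelled.
    """

    name: str
    checkpoints: tuple[CheckpointSegment, ...]
    total_km: float
    time_limit_hours: float | None = None

    def __post_init__(self) -> None:
        cps = self.checkpoints
        if len(cps) < 2:
            raise CourseValidationError(
                f"course needs at least 2 checkpoints, got {len(cps)}"
            )
        for pos, cp in enumerate(cps, start=1):
            if cp.index != pos:
                raise CourseValidationError(
                    f"checkpoint indices must be contiguous 1..N; "
                    f"position {pos} has index {cp.index}"
                )
            if not cp.segment_km > 0:
                raise CourseValidationError(
                    f"segment distance of checkpoint {cp.index} must be "
                    f"strictly positive, got {cp.segment_km}"
                )
        cum = np.cumsum([cp.segment_km for cp in cps])
        for cp, expected in zip(cps, cum):
            if abs(cp.cumulative_km - expected) > _REL_TOL * max(1.0, expected):
                raise CourseValidationError(
                    f"cumulative distance of checkpoint {cp.index} is "
                    f"{cp.cumulative_km} km but the segment sum is {expected} km"
                )
        if abs(cum[-1] - self.total_km) > _REL_TOL * max(1.0, self.total_km):
            raise CourseValidationError(
                f"declared total distance {self.total_km} km does not match "
                f"the segment sum {cum[-1]} km"
            )
        if self.time_limit_hours is not None and not self.time_limit_hours > 0:
            raise CourseValidationError(
                f"time limit must be positive, got {self.time_limit_hours}"
            )

    @property
    def n_checkpoints(self) -> int:
        return len(self.checkpoints)

    @property
    def segment_km_array(self) -> np.ndarray:
        return np.array([cp.segment_km for cp in self.checkpoints])

    @property
    def segment_m_array(self) -> np.ndarray:
        return self.segment_km_array * 1000.0

    @property
    def cumulative_m_array(self) -> np.ndarray:
        return np.cumsum(self.segment_m_array)

    @property
    def total_m(self) -> float:
        return self.total_km * 1000.0

    @property
    def time_limit_s(self) -> int | None:
        if self.time_limit_hours is None:
            return None
        return int(round(self.time_limit_hours * 3600))


def course_from_segments(
    name: str,
    segment_km: list[float] | tuple[float, ...] | np.ndarray,
    labels: list[str] | None = None,
    time_limit_hours: float | None = None,
    total_km: float | None = None,
) -> CourseDefinition:
    """Build a validated course from segment lengths.

    ``total_km`` defaults to the segment sum; if given explicitly it must
    agree with the sum (this is how inconsistent course files are caught).
    """
    segment_km = [float(d) for d in segment_km]
    if labels is None:
        labels = [f"segment {j}" for j in range(1, len(segment_km) + 1)]
    if len(labels) != len(segment_km):
        raise CourseFormatError(
            f"{len(labels)} labels for {len(segment_km)} segments"
        )
    cum = np.cumsum(segment_km)
    cps = tuple(
        CheckpointSegment(index=j, label=lab, segment_km=d, cumulative_km=float(c))
        for j, (lab, d, c) in enumerate(zip(labels, segment_km, cum), start=1)
    )
    if total_km is None:
        total_km = float(cum[-1]) if len(cum) else 0.0
    return CourseDefinition(
        name=name,
        checkpoints=cps,
        total_km=float(total_km),
        time_limit_hours=time_limit_hours,
    )


def _parse_course_dict(raw: dict) -> CourseDefinition:
    for key in ("name", "checkpoints"):
        if key not in raw:
            raise CourseFormatError(f"course file is missing field '{key}'")
    cps = raw["checkpoints"]
    if not isinstance(cps, list) or not cps:
        raise CourseFormatError("field 'checkpoints' must be a non-empty list")
    segs, labels = [], []
    for k, cp in enumerate(cps):
        for key in ("index", "segment_km"):
            if key not in cp:
                raise CourseFormatError(
                    f"checkpoint entry {k} is missing field '{key}'"
                )
        try:
            segs.append(float(cp["segment_km"]))
        except (TypeError, ValueError) as exc:
            raise CourseFormatError(
                f"checkpoint entry {k}: segment_km is not a number "
                f"({cp['segment_km']!r})"
            ) from exc
        labels.append(str(cp.get("label", f"segment {cp['index']}")))
    declared = [int(cp["index"]) for cp in cps]
    if declared != list(range(1, len(cps) + 1)):
        raise CourseValidationError(
            f"checkpoint indices must be 1..{len(cps)} in order, got {declared}"
        )
    total = raw.get("total_km")
    return course_from_segments(
        name=str(raw["name"]),
        segment_km=segs,
        labels=labels,
        time_limit_hours=raw.get("time_limit_hours"),
        total_km=None if total is None else float(total),
    )


def load_course(path: str | Path) -> CourseDefinition:
    """Load a course from a JSON file (see the bundled ``spartathlon.json``).

    Cumulative distances are always recomputed from the segments, never read
    from the file.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise CourseFormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(raw, dict):
        raise CourseFormatError(f"{path}: top level must be a JSON object")
    return _parse_course_dict(raw)


def spartathlon_course() -> CourseDefinition:
    """The bundled 10-checkpoint, 246.8 km Athens-Sparta course (36 h limit)."""
    raw = json.loads(
        resources.files("spartapace").joinpath("data/spartathlon.json").read_text()
    )
    return _parse_course_dict(raw)
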