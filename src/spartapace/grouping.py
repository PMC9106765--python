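"""Age-group and performance-quartile stratification.

Age bins: <30, 30-34, 35-39, 40-44, 45-49, 50-54, 55-59, 60+ (the open end
bins absorb the sparse tails); a missing age maps to "missing" and drops the
runner from age-based inference only.

Performance groups are quartiles of average race speed, fastest first:
HL (high level) = fastest quarter, then MHL, MLL, LL.  The quartile wording
in race-analysis papers is often ambiguous about direction; here HL
unambiguously means the fastest runners.  Ties are broken by a stable sort
on runner id so assignments never depend on input order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "AGE_GROUP_LABELS",
    "PERFORMANCE_LABELS",
    "GroupingError",
    "add_group_assignments",
    "assign_age_group",
    "assign_performance_groups",
]

AGE_GROUP_LABELS = (
    "<30", "30-34", "35-39", "40-44", "45-49", "50-54", "55-59", "60+",
)
_AGE_EDGES = (30, 35, 40, 45, 50, 55, 60)  # left-closed bin edges after "<30"

PERFORMANCE_LABELS = ("HL", "MHL", "MLL", "LL")


class GroupingError(ValueError):
    """Raised when a stratification cannot be formed (e.g. <4 runners)."""


def assign_age_group(age: int | float | None) -> str:
    """Map an age in years to its bin label; None/NaN -> 'missing'."""
    if age is None or (isinstance(age, float) and np.isnan(age)):
        return "missing"
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    if age < 30:
        return "<30"
    for lo, label in zip(_AGE_EDGES, AGE_GROUP_LABELS[1:]):
        if age < lo + 5:
            return label
    return "60+"


def assign_performance_groups(
    runner_ids: list[str] | np.ndarray,
    average_speeds: list[float] | np.ndarray,
) -> dict[str, str]:
    """Quartile runners by average race speed, fastest first.

    Returns ``{runner_id: label}`` with group sizes differing from n/4 by at
    most one (the remainder goes to the faster groups).  Deterministic under
    ties and input permutation: runners are ranked by (speed desc, id asc).
    """
    ids = [str(r) for r in runner_ids]
    speeds = np.asarray(average_speeds, dtype=float)
    n = len(ids)
    if n != speeds.size:
        raise ValueError("runner_ids and average_speeds differ in length")
    if len(set(ids)) != n:
        raise ValueError("runner ids must be unique within a grouping scope")
    if n < 4:
        raise GroupingError(f"need at least 4 runners to form quartiles, got {n}")
    order = sorted(range(n), key=lambda i: (-speeds[i], ids[i]))
    out: dict[str, str] = {}
    for label, chunk in zip(PERFORMANCE_LABELS, np.array_split(order, 4)):
        for i in chunk:
            out[ids[i]] = label
    return out


def add_group_assignments(
    metrics: pd.DataFrame, scope: str = "overall"
) -> pd.DataFrame:
    """Return runner_id/age_group/performance_group from a metrics table.

    ``scope`` is ``"overall"`` (quartiles over the pooled cohort) or
    ``"within_sex"`` (quartiles formed separately per sex).
    """
    if scope not in ("overall", "within_sex"):
        raise ValueError(f"unknown grouping scope {scope!r}")
    out = pd.DataFrame(
        {
            "runner_id": metrics["runner_id"].astype(str),
            "age_group": [assign_age_group(a) for a in metrics["age"]],
        }
    )
    if scope == "overall":
        mapping = assign_performance_groups(
            out["runner_id"], metrics["average_speed_ms"]
        )
    else:
        mapping = {}
        for _, sub in metrics.groupby("sex"):
            mapping.update(
                assign_performance_groups(
                    sub["runner_id"].astype(str), sub["average_speed_ms"]
                )
            )
    out["performance_group"] = out["runner_id"].map(mapping)
    return out
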