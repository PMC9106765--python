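"""Runner split-time records: parsing, validation, exclusion accounting.

The splits file is a CSV with header ``runner_id,sex,age,cp1,...,cpN`` where
``cpN`` is the finish.  Times are "HH:MM:SS" (hours may exceed 24) or plain
integer seconds; an empty cell is a missing value.  Race timing is at 1 s
resolution, so times are stored as integer seconds throughout — telescoping
sums of segment times are then exact.

A row enters the analysed cohort only if the runner finished and recorded
every split; everything else is excluded, one reason per row, and counted in
an :class:`ExclusionReport` so that included + excluded = rows read.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .course import CourseDefinition

__all__ = [
    "Cohort",
    "ExclusionReport",
    "RunnerRecord",
    "SplitsFormatError",
    "format_time",
    "load_splits",
    "parse_time",
    "segment_times",
    "write_splits",
]

EXCLUSION_REASONS = (
    "did_not_finish",
    "missing_split",
    "unparseable",
    "non_monotone",
    "over_time_limit",
)


class SplitsFormatError(ValueError):
    """The splits file as a whole cannot be read (bad header, empty file)."""


@dataclass(frozen=True)
class RunnerRecord:
    """One finisher: sex, age (optional) and cumulative times at every checkpoint.

    ``cumulative_s[j-1]`` is the elapsed time in seconds at checkpoint ``j``;
    the last entry is the finish time.  Validated records have no missing
    entries and strictly increasing positive times.
    """

    runner_id: str
    sex: str  # 'M' or 'F'
    age: int | None
    cumulative_s: tuple[int, ...]


@dataclass
class ExclusionReport:
    """Row-level accounting for one splits file."""

    n_input: int = 0
    n_included: int = 0
    counts: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in EXCLUSION_REASONS}
    )
    excluded_rows: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
            "counts": dict(self.counts),
        }


@dataclass
class Cohort:
    """A course plus the validated records analysed against it."""

    course: CourseDefinition
    records: list[RunnerRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def cumulative_matrix(self) -> np.ndarray:
        """(n_runners, n_checkpoints) int array of cumulative seconds."""
        return np.array([r.cumulative_s for r in self.records], dtype=np.int64)

    def sexes(self) -> np.ndarray:
        return np.array([r.sex for r in self.records])

    def ages(self) -> np.ndarray:
        return np.array(
            [np.nan if r.age is None else r.age for r in self.records], dtype=float
        )


def parse_time(token: str) -> int | None:
    """Parse 'HH:MM:SS' or plain seconds; '' -> None; garbage -> ValueError."""
    token = token.strip()
    if not token:
        return None
    if ":" in token:
        parts = token.split(":")
        if len(parts) != 3:
            raise ValueError(f"bad time token {token!r}")
        try:
            h, m, s = (int(p) for p in parts)
        except ValueError as exc:
            raise ValueError(f"bad time token {token!r}") from exc
        if not (0 <= m < 60 and 0 <= s < 60 and h >= 0):
            raise ValueError(f"bad time token {token!r}")
        return h * 3600 + m * 60 + s
    try:
        return int(token)
    except ValueError as exc:
        raise ValueError(f"bad time token {token!r}") from exc


def format_time(seconds: int) -> str:
    h, rem = divmod(int(seconds), 3600)
    m, s = divmod(rem, 60)
    return f"{h:02d}:{m:02d}:{s:02d}"


def _parse_sex(token: str) -> str:
    t = token.strip().upper()
    if t in ("M", "MALE"):
        return "M"
    if t in ("F", "W", "FEMALE"):
        return "F"
    raise ValueError(f"bad sex token {token!r}")


def _classify_row(
    times: list[int | None], course: CourseDefinition
) -> str | None:
    """Return an exclusion reason for a parsed row, or None if it validates."""
    if times[-1] is None:
        return "did_not_finish"
    if any(t is None for t in times[:-1]):
        return "missing_split"
    vals = [int(t) for t in times]  # type: ignore[arg-type]
    if vals[0] <= 0 or any(b <= a for a, b in zip(vals, vals[1:])):
        return "non_monotone"
    limit = course.time_limit_s
    if limit is not None and vals[-1] > limit:
        return "over_time_limit"
    return None


def load_splits(
    path: str | Path, course: CourseDefinition
) -> tuple[Cohort, ExclusionReport]:
    """Read a splits CSV and validate each row against the course.

    Unparseable cells exclude the row (reason ``unparseable``) rather than
    aborting the load; a malformed header or an empty file is a hard error.
    """
    path = Path(path)
    n = course.n_checkpoints
    expected_header = ["runner_id", "sex", "age"] + [f"cp{j}" for j in range(1, n + 1)]
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SplitsFormatError(f"{path}: empty file") from None
        if [h.strip() for h in header] != expected_header:
            raise SplitsFormatError(
                f"{path}: header {header!r} does not match expected "
                f"{expected_header!r}"
            )
        report = ExclusionReport()
        records: list[RunnerRecord] = []
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            report.n_input += 1
            if len(row) != len(expected_header):
                report.counts["unparseable"] += 1
                report.excluded_rows.append((row[0] if row else "?", "unparseable"))
                continue
            runner_id = row[0].strip()
            try:
                sex = _parse_sex(row[1])
                age_tok = row[2].strip()
                age = int(age_tok) if age_tok else None
                if age is not None and age < 0:
                    raise ValueError(f"negative age {age}")
                times = [parse_time(tok) for tok in row[3:]]
            except ValueError:
                report.counts["unparseable"] += 1
                report.excluded_rows.append((runner_id, "unparseable"))
                continue
            reason = _classify_row(times, course)
            if reason is not None:
                report.counts[reason] += 1
                report.excluded_rows.append((runner_id, reason))
                continue
            records.append(
                RunnerRecord(
                    runner_id=runner_id,
                    sex=sex,
                    age=age,
                    cumulative_s=tuple(int(t) for t in times),  # type: ignore[arg-type]
                )
            )
        report.n_included = len(records)
    if report.n_input == 0:
        raise SplitsFormatError(f"{path}: no data rows")
    cohort = Cohort(course=course, records=records, provenance=str(path))
    return cohort, report


def write_splits(path: str | Path, cohort: Cohort) -> None:
    """Write a cohort back to the splits CSV schema (times as HH:MM:SS)."""
    n = cohort.course.n_checkpoints
    header = ["runner_id", "sex", "age"] + [f"cp{j}" for j in range(1, n + 1)]
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in cohort.records:
            writer.writerow(
                [r.runner_id, r.sex, "" if r.age is None else r.age]
                + [format_time(t) for t in r.cumulative_s]
            )


def segment_times(record: RunnerRecord) -> np.ndarray:
    """Per-segment times t_j = T_j - T_{j-1} (with T_0 = 0), integer seconds."""
    return np.diff(np.asarray(record.cumulative_s, dtype=np.int64), prepend=0)
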