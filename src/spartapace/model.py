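"""Cohort-level pacing model: the full inferential battery behind one
``fit()`` call, statsmodels-style.

``PacingModel`` wraps a validated cohort, computes the per-runner pacing
metrics on construction, and ``fit()`` runs the analysis stages in order:

1. KS normality check on ACCS (advisory; never gates later stages);
2. grouping into age bins and performance quartiles;
3. split-plot ANOVA on absolute CCS (checkpoint within, sex between), with
   sex-vs-sex post-hocs at each checkpoint (Bonferroni family = N
   checkpoints) and all-pairs paired checkpoint post-hocs (family N(N-1)/2);
4. two-way ANOVA age-group x sex on ACCS (runners with missing age dropped
   from this stage only, with the dropped count reported);
5. two-way ANOVA performance-group x sex on ACCS, with pairwise
   performance-group post-hocs within each sex (family 6 per sex).

A stage that cannot run on the given cohort (e.g. quartiles on fewer than 4
runners) is recorded in ``stage_errors`` and skipped; the remaining stages
still execute.  Alpha is 0.05 by default and applies to every test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .anova import (
    AnovaTable,
    KSResult,
    PosthocResult,
    ks_normality,
    mixed_anova,
    posthoc_between_at_each_level,
    posthoc_pairwise_independent,
    posthoc_pairwise_paired,
    twoway_anova,
)
from .course import CourseDefinition, spartathlon_course
from .grouping import add_group_assignments
from .metrics import cohort_metrics
from .records import Cohort, ExclusionReport, load_splits

__all__ = ["PacingModel", "PacingResults"]

SCHEMA_VERSION = "1.0"


class PacingModel:
    """Pacing analysis of a checkpoint-split cohort.

    Parameters
    ----------
    cohort
        Validated cohort (course + records).
    group_scope
        ``"overall"`` forms performance quartiles over the pooled cohort,
        ``"within_sex"`` forms them separately per sex.
    alpha
        Significance level for every test in the battery.
    shape_tolerance
        Equality band (percent of mean speed) for pacing-shape
        classification.
    """

    def __init__(
        self,
        cohort: Cohort,
        *,
        group_scope: str = "overall",
        alpha: float = 0.05,
        shape_tolerance: float = 2.0,
    ) -> None:
        if not 0 < alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {alpha}")
        if shape_tolerance < 0:
            raise ValueError("shape tolerance must be non-negative")
        if len(cohort) == 0:
            raise ValueError("cohort is empty")
        self.cohort = cohort
        self.course = cohort.course
        self.group_scope = group_scope
        self.alpha = alpha
        self.shape_tolerance = shape_tolerance
        self.exclusions: ExclusionReport | None = None
        self.profiles = cohort_metrics(cohort, tolerance=shape_tolerance)
        n = self.course.n_checkpoints
        self._speed_cols = [f"cp{j}_speed" for j in range(1, n + 1)]
        self._ccs_cols = [f"cp{j}_ccs_signed" for j in range(1, n + 1)]
        self._ccs_abs = np.abs(self.profiles[self._ccs_cols].to_numpy())
        self._sex = self.profiles["sex"].to_numpy()

    @classmethod
    def from_csv(
        cls,
        splits_path: str | Path,
        course: CourseDefinition | None = None,
        **kwargs: Any,
    ) -> "PacingModel":
        """Build a model straight from a splits CSV (default course:
        the bundled Spartathlon definition)."""
        course = course or spartathlon_course()
        cohort, report = load_splits(splits_path, course)
        if len(cohort) == 0:
            raise ValueError(
                f"{splits_path}: no valid rows "
                f"(exclusions: {report.counts})"
            )
        model = cls(cohort, **kwargs)
        model.exclusions = report
        return model

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "PacingResults":
        res = PacingResults(model=self)
        n_cp = self.course.n_checkpoints
        cp_names = [f"cp{j}" for j in range(1, n_cp + 1)]

        def stage(name, fn):
            try:
                fn()
                res.n_used_per_stage.setdefault(name, len(self.cohort))
            except Exception as exc:  # noqa: BLE001 - surfaced, not silenced
                res.stage_errors[name] = f"{type(exc).__name__}: {exc}"

        def _normality():
            res.ks = ks_normality(self.profiles["accs"].to_numpy())

        def _grouping():
            res.groups = add_group_assignments(self.profiles, self.group_scope)

        def _checkpoint_sex():
            res.anova_checkpoint_sex = mixed_anova(
                self._ccs_abs, self._sex,
                within_name="checkpoint", between_name="sex",
            )
            res.posthoc_sex_by_checkpoint = posthoc_between_at_each_level(
                self._ccs_abs, self._sex, cp_names, self.alpha,
                family="sex at each checkpoint (abs CCS)",
            )
            res.posthoc_checkpoint_pairs = posthoc_pairwise_paired(
                self._ccs_abs, cp_names, self.alpha,
                family="checkpoint pairs (abs CCS)",
            )

        def _age_sex():
            if res.groups is None:
                raise RuntimeError("grouping stage did not run")
            keep = res.groups["age_group"] != "missing"
            n_drop = int((~keep).sum())
            table = twoway_anova(
                self.profiles.loc[keep.to_numpy(), "accs"],
                res.groups.loc[keep, "age_group"],
                self.profiles.loc[keep.to_numpy(), "sex"],
                a_name="age_group", b_name="sex",
            )
            table.n_dropped = n_drop
            res.anova_age_sex = table
            res.n_used_per_stage["age_sex_anova"] = int(keep.sum())

        def _performance_sex():
            if res.groups is None:
                raise RuntimeError("grouping stage did not run")
            perf = res.groups["performance_group"]
            res.anova_performance_sex = twoway_anova(
                self.profiles["accs"], perf, self.profiles["sex"],
                a_name="performance_group", b_name="sex",
            )
            res.posthoc_performance_within_sex = {}
            for sex in sorted(set(self._sex.tolist())):
                mask = self._sex == sex
                by_level = {
                    lev: self.profiles.loc[
                        mask & (perf == lev).to_numpy(), "accs"
                    ].to_numpy()
                    for lev in sorted(set(perf[mask].tolist()))
                }
                res.posthoc_performance_within_sex[sex] = (
                    posthoc_pairwise_independent(
                        by_level, self.alpha,
                        family=f"performance groups within sex {sex} (ACCS)",
                    )
                )

        stage("normality", _normality)
        stage("grouping", _grouping)
        stage("checkpoint_sex_anova", _checkpoint_sex)
        if "grouping" in res.stage_errors:
            res.stage_errors.setdefault(
                "age_sex_anova", "skipped: grouping stage failed"
            )
            res.stage_errors.setdefault(
                "performance_sex_anova", "skipped: grouping stage failed"
            )
        else:
            stage("age_sex_anova", _age_sex)
            stage("performance_sex_anova", _performance_sex)
        return res


@dataclass
class PacingResults:
    """Everything ``PacingModel.fit`` produces."""

    model: PacingModel
    ks: KSResult | None = None
    groups: pd.DataFrame | None = None
    anova_checkpoint_sex: AnovaTable | None = None
    anova_age_sex: AnovaTable | None = None
    anova_performance_sex: AnovaTable | None = None
    posthoc_sex_by_checkpoint: PosthocResult | None = None
    posthoc_checkpoint_pairs: PosthocResult | None = None
    posthoc_performance_within_sex: dict[str, PosthocResult] = field(
        default_factory=dict
    )
    stage_errors: dict[str, str] = field(default_factory=dict)
    n_used_per_stage: dict[str, int] = field(default_factory=dict)

    # -- derived summaries ------------------------------------------------

    @property
    def profiles(self) -> pd.DataFrame:
        return self.model.profiles

    def mean_profile(self, sex: str | None = None) -> np.ndarray:
        """Cohort mean checkpoint-speed profile (m/s), optionally per sex."""
        df = self.profiles
        if sex is not None:
            df = df[df["sex"] == sex]
        return df[self.model._speed_cols].to_numpy().mean(axis=0)

    def accs_by_group(self) -> pd.DataFrame:
        """Mean ACCS per sex x performance group (long format)."""
        if self.groups is None:
            raise RuntimeError("grouping stage did not run")
        df = self.profiles[["runner_id", "sex", "accs"]].merge(
            self.groups[["runner_id", "performance_group"]], on="runner_id"
        )
        return (
            df.groupby(["sex", "performance_group"], observed=True)["accs"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )

    def shape_census(self) -> dict[str, int]:
        counts = self.profiles["shape_label"].value_counts().to_dict()
        return {str(k): int(v) for k, v in sorted(counts.items())}

    # -- reporting --------------------------------------------------------

    def cohort_summary(self) -> dict:
        df = self.profiles
        by_sex = {}
        for sex, sub in df.groupby("sex"):
            by_sex[str(sex)] = {
                "n": int(len(sub)),
                "mean_average_speed_ms": float(sub["average_speed_ms"].mean()),
                "mean_checkpoint_speeds_ms": [
                    float(v)
                    for v in sub[self.model._speed_cols].mean(axis=0)
                ],
            }
        return {"n_total": int(len(df)), "by_sex": by_sex}

    def to_report(self) -> dict:
        """JSON-serialisable analysis report (deterministic key order,
        NaN rendered as null)."""
        m = self.model
        report: dict[str, Any] = {
            "schema_version": SCHEMA_VERSION,
            "software": {"package": "spartapace", "version": __version__},
            "config": {
                "course": m.course.name,
                "n_checkpoints": m.course.n_checkpoints,
                "group_scope": m.group_scope,
                "alpha": m.alpha,
                "shape_tolerance_pct": m.shape_tolerance,
                "provenance": m.cohort.provenance,
            },
            "cohort_summary": self.cohort_summary(),
            "shape_census": self.shape_census(),
            "exclusions": m.exclusions.to_dict() if m.exclusions else None,
            "ks_accs": self.ks.to_dict() if self.ks else None,
            "anova_tables": {
                name: table.to_dict() if table else None
                for name, table in (
                    ("checkpoint_sex", self.anova_checkpoint_sex),
                    ("age_sex", self.anova_age_sex),
                    ("performance_sex", self.anova_performance_sex),
                )
            },
            "posthoc": {
                "sex_by_checkpoint": (
                    self.posthoc_sex_by_checkpoint.to_dict()
                    if self.posthoc_sex_by_checkpoint
                    else None
                ),
                "checkpoint_pairs": (
                    self.posthoc_checkpoint_pairs.to_dict()
                    if self.posthoc_checkpoint_pairs
                    else None
                ),
                "performance_within_sex": {
                    sex: ph.to_dict()
                    for sex, ph in sorted(
                        self.posthoc_performance_within_sex.items()
                    )
                },
            },
            "n_used_per_stage": dict(sorted(self.n_used_per_stage.items())),
            "stage_errors": dict(sorted(self.stage_errors.items())),
        }
        return report

    def summary(self) -> str:
        """Human-readable multi-table summary."""
        m = self.model
        lines = [
            "Checkpoint pacing analysis",
            "=" * 60,
            f"course: {m.course.name} "
            f"({m.course.n_checkpoints} checkpoints, {m.course.total_km} km)",
            f"runners: {len(m.cohort)}  "
            f"(alpha={m.alpha}, grouping scope={m.group_scope})",
            "",
            "Shape census: "
            + ", ".join(f"{k}={v}" for k, v in self.shape_census().items()),
        ]
        if self.ks is not None:
            lines.append(
                f"KS normality of ACCS: D={self.ks.statistic:.4f} "
                f"p={self.ks.p:.4g} (advisory)"
                if not self.ks.degenerate
                else "KS normality of ACCS: degenerate (zero variance)"
            )
        for title, table in (
            ("Split-plot ANOVA on |CCS| (checkpoint x sex)",
             self.anova_checkpoint_sex),
            ("Two-way ANOVA on ACCS (age group x sex)", self.anova_age_sex),
            ("Two-way ANOVA on ACCS (performance group x sex)",
             self.anova_performance_sex),
        ):
            if table is None:
                continue
            lines += ["", title, "-" * len(title)]
            with pd.option_context("display.width", 120):
                lines.append(
                    table.to_frame().to_string(index=False, float_format="%.4g")
                )
            if table.n_dropped:
                lines.append(f"(dropped {table.n_dropped} runners: missing age)")
            for w in table.warnings:
                lines.append(f"warning: {w}")
        if self.stage_errors:
            lines += ["", "Stages not run:"]
            lines += [f"  {k}: {v}" for k, v in sorted(self.stage_errors.items())]
        return "\n".join(lines)
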