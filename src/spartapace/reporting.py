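"""Cohort summary tables and analysis artifacts.

``summarize_cohort`` emits the descriptive table race analyses publish:
per sex and per checkpoint, the mean/SD/min/max checkpoint speed, plus an
"average" row for the average race speed.  SDs are sample (n-1) SDs.

``write_artifacts`` persists a fitted analysis as metrics.csv, groups.csv,
report.json and report.txt.  report.json is deterministic (sorted keys, no
timestamps) so fixed inputs yield byte-identical artifacts.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import cohort_metrics
from .model import PacingResults
from .records import Cohort

__all__ = ["summarize_cohort", "write_artifacts", "plot_ccs"]


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Descriptive speed table: rows (sex, checkpoint 1..N + 'average'),
    columns mean/sd/min/max in m/s."""
    metrics = cohort_metrics(cohort)
    n_cp = cohort.course.n_checkpoints
    rows = []
    for sex in ("M", "F"):
        sub = metrics[metrics["sex"] == sex]
        if sub.empty:
            warnings.warn(f"no runners of sex {sex!r}; stratum omitted")
            continue
        for j in range(1, n_cp + 1):
            v = sub[f"cp{j}_speed"].to_numpy()
            rows.append(_summary_row(sex, str(j), v))
        rows.append(_summary_row(sex, "average", sub["average_speed_ms"].to_numpy()))
    return pd.DataFrame(rows)


def _summary_row(sex: str, checkpoint: str, v: np.ndarray) -> dict:
    return {
        "sex": sex,
        "checkpoint": checkpoint,
        "mean_ms": float(v.mean()),
        "sd_ms": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "min_ms": float(v.min()),
        "max_ms": float(v.max()),
        "n": int(v.size),
    }


def write_artifacts(results: PacingResults, outdir: str | Path) -> dict[str, Path]:
    """Write metrics.csv, groups.csv, report.json, report.txt; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["metrics"] = outdir / "metrics.csv"
    results.profiles.to_csv(paths["metrics"], index=False)

    if results.groups is not None:
        paths["groups"] = outdir / "groups.csv"
        results.groups.to_csv(paths["groups"], index=False)

    paths["report_json"] = outdir / "report.json"
    paths["report_json"].write_text(
        json.dumps(results.to_report(), indent=2, sort_keys=True) + "\n"
    )

    paths["report_txt"] = outdir / "report.txt"
    paths["report_txt"].write_text(results.summary() + "\n")
    return paths


def plot_ccs(results: PacingResults, path: str | Path) -> None:
    """Optional PNG of the mean signed CCS curve by sex (error bars = SD).

    Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = results.profiles
    n_cp = results.model.course.n_checkpoints
    cols = [f"cp{j}_ccs_signed" for j in range(1, n_cp + 1)]
    x = np.arange(1, n_cp + 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    for sex, marker in (("M", "o"), ("F", "s")):
        sub = df[df["sex"] == sex]
        if sub.empty:
            continue
        mean = sub[cols].mean(axis=0)
        sd = sub[cols].std(axis=0, ddof=1)
        ax.errorbar(x, mean, yerr=sd, marker=marker, capsize=3, label=sex)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel("checkpoint")
    ax.set_ylabel("CCS (% of average race speed)")
    ax.set_xticks(x)
    ax.legend(title="sex")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
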