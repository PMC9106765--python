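"""Fixed-effects ANOVA engine: split-plot (mixed between-within) and two-way
factorial decompositions, with classical eta-squared, Bonferroni adjustment,
pairwise post-hoc t-tests and a Kolmogorov-Smirnov normality check.

The split-plot design has one between-subjects factor (e.g. sex) and one
within-subjects factor measured on every subject (e.g. checkpoint).  Because
every subject contributes a complete row, the subject x within-level layout
has proportional cell frequencies even when group sizes are unbalanced, so
the weighted-means decomposition below is orthogonal and the sums of squares
add exactly to the total:

    between stratum:  SS_A (groups) + SS_subjects-within-groups
    within stratum:   SS_W (within factor) + SS_AxW + SS_W x subjects-within

F for the between factor uses the subjects-within-groups mean square; the
within factor and the interaction are tested against the within-error mean
square.  No sphericity correction is applied by default; Greenhouse-Geisser
epsilon-adjusted p-values are available as an option.

The two-way factorial (used on the scalar pacing index with unbalanced
groups) uses Type III sums of squares via effect-coded least squares: each
effect's SS is the increase in residual SS when its columns are dropped from
the full model.  Type III SS are not additive under unbalance; the table
carries an ``additive`` flag that holds for balanced designs.

Eta-squared is classical (SS_effect / SS_total, magnitude labels
negligible < 0.01 <= small < 0.06 <= medium < 0.14 <= large); partial
eta-squared (SS_effect / (SS_effect + SS_error)) is also reported since
mixed-design conventions differ.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaTable",
    "Comparison",
    "DesignError",
    "EffectRow",
    "KSResult",
    "PosthocResult",
    "bonferroni",
    "effect_size_label",
    "eta_squared",
    "ks_normality",
    "mixed_anova",
    "posthoc_between_at_each_level",
    "posthoc_pairwise_independent",
    "posthoc_pairwise_paired",
    "twoway_anova",
]


class DesignError(ValueError):
    """The data cannot support the requested design (missing cells, etc.)."""


# ---------------------------------------------------------------------------
# result containers


@dataclass
class EffectRow:
    name: str
    ss: float
    df: int
    ms: float
    f: float  # nan when the error stratum has zero variance
    p: float
    eta_sq: float
    eta_label: str
    partial_eta_sq: float = float("nan")
    error_term: str = ""

    @property
    def undefined(self) -> bool:
        return not np.isfinite(self.f)


@dataclass
class AnovaTable:
    design: str
    effects: list[EffectRow]
    error_terms: list[EffectRow]
    total_ss: float
    total_df: int
    n_subjects: int
    n_dropped: int = 0
    additive: bool = True
    warnings: list[str] = field(default_factory=list)

    def effect(self, name: str) -> EffectRow:
        for row in self.effects:
            if row.name == name:
                return row
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.effects + self.error_terms:
            rows.append(
                {
                    "source": r.name,
                    "ss": r.ss,
                    "df": r.df,
                    "ms": r.ms,
                    "F": r.f,
                    "p": r.p,
                    "eta_sq": r.eta_sq,
                    "eta_label": r.eta_label,
                    "partial_eta_sq": r.partial_eta_sq,
                }
            )
        rows.append(
            {
                "source": "total",
                "ss": self.total_ss,
                "df": self.total_df,
                "ms": np.nan,
                "F": np.nan,
                "p": np.nan,
                "eta_sq": np.nan,
                "eta_label": "",
                "partial_eta_sq": np.nan,
            }
        )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, float) and not np.isfinite(x):
                return None
            return x

        return {
            "design": self.design,
            "n_subjects": self.n_subjects,
            "n_dropped": self.n_dropped,
            "total_ss": self.total_ss,
            "total_df": self.total_df,
            "additive": self.additive,
            "warnings": list(self.warnings),
            "effects": [
                {
                    "source": r.name,
                    "ss": r.ss,
                    "df": r.df,
                    "ms": clean(r.ms),
                    "F": clean(r.f),
                    "p": clean(r.p),
                    "eta_sq": clean(r.eta_sq),
                    "eta_label": r.eta_label,
                    "partial_eta_sq": clean(r.partial_eta_sq),
                    "error_term": r.error_term,
                }
                for r in self.effects
            ],
            "error_terms": [
                {"source": r.name, "ss": r.ss, "df": r.df, "ms": clean(r.ms)}
                for r in self.error_terms
            ],
        }


@dataclass
class Comparison:
    level_a: str
    level_b: str
    mean_a: float
    mean_b: float
    mean_diff: float
    t: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass
class PosthocResult:
    family: str
    alpha: float
    family_size: int
    comparisons: list[Comparison]

    def get(self, level_a: str, level_b: str) -> Comparison:
        for c in self.comparisons:
            if (c.level_a, c.level_b) == (level_a, level_b) or (
                c.level_b, c.level_a
            ) == (level_a, level_b):
                return c
        raise KeyError((level_a, level_b))

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, float) and not np.isfinite(x):
                return None
            return x

        return {
            "family": self.family,
            "alpha": self.alpha,
            "family_size": self.family_size,
            "comparisons": [
                {
                    "level_a": c.level_a,
                    "level_b": c.level_b,
                    "mean_a": c.mean_a,
                    "mean_b": c.mean_b,
                    "mean_diff": c.mean_diff,
                    "t": clean(c.t),
                    "p_raw": clean(c.p_raw),
                    "p_adjusted": clean(c.p_adjusted),
                    "significant": c.significant,
                }
                for c in self.comparisons
            ],
        }


@dataclass
class KSResult:
    statistic: float
    p: float
    n: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": None if not np.isfinite(self.statistic) else self.statistic,
            "p": None if not np.isfinite(self.p) else self.p,
            "n": self.n,
            "degenerate": self.degenerate,
        }


# ---------------------------------------------------------------------------
# effect-size helpers


def effect_size_label(eta_sq: float) -> str:
    """Magnitude label with cutoffs inclusive at the lower edge."""
    if not np.isfinite(eta_sq):
        return "undefined"
    if eta_sq < 0.01:
        return "negligible"
    if eta_sq < 0.06:
        return "small"
    if eta_sq < 0.14:
        return "medium"
    return "large"


def eta_squared(ss_effect: float, ss_total: float) -> tuple[float, str]:
    """Classical eta-squared SS_effect/SS_total with its magnitude label.

    A zero total SS (all observations identical) yields (nan, "undefined")
    rather than an error.
    """
    if ss_total == 0:
        return float("nan"), "undefined"
    if ss_total < 0 or ss_effect < 0 or ss_effect > ss_total * (1 + 1e-12):
        raise ValueError(
            f"need 0 <= ss_effect <= ss_total, got {ss_effect} / {ss_total}"
        )
    val = ss_effect / ss_total
    return val, effect_size_label(val)


def bonferroni(p_raw: list[float] | np.ndarray) -> np.ndarray:
    """p_adj[i] = min(1, p_raw[i] * m) over the family of m comparisons."""
    p = np.asarray(p_raw, dtype=float)
    finite = p[np.isfinite(p)]
    if np.any(finite < 0) or np.any(finite > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


# ---------------------------------------------------------------------------
# normality


def ks_normality(values: list[float] | np.ndarray) -> KSResult:
    """One-sample KS test against a normal with the sample mean and SD.

    Advisory only; the parameters are estimated from the data, so the test
    is anti-conservative in the strict sense.  All-equal input returns a
    degenerate-flagged result instead of an error.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError(f"need at least 5 values for the KS check, got {x.size}")
    sd = float(x.std(ddof=1))
    if sd == 0:
        return KSResult(float("nan"), float("nan"), x.size, degenerate=True)
    stat, p = stats.kstest(x, "norm", args=(float(x.mean()), sd))
    return KSResult(float(stat), float(p), x.size)


# ---------------------------------------------------------------------------
# split-plot (mixed between-within) ANOVA


def _f_and_p(ss: float, df: int, ms_err: float, df_err: int) -> tuple[float, float]:
    if df <= 0 or df_err <= 0 or ms_err <= 0:
        return float("nan"), float("nan")
    f = (ss / df) / ms_err
    return f, float(stats.f.sf(f, df, df_err))


def _gg_epsilon(values: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the within-subject covariance matrix."""
    k = values.shape[1]
    s = np.cov(values, rowvar=False)
    mean_diag = np.trace(s) / k
    mean_all = s.mean()
    row_means = s.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (
        (s**2).sum() - 2 * k * (row_means**2).sum() + k**2 * mean_all**2
    )
    if den <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / (k - 1), num / den)))


def mixed_anova(
    values: np.ndarray,
    between: list[str] | np.ndarray,
    *,
    within_name: str = "checkpoint",
    between_name: str = "sex",
    gg_correction: bool = False,
) -> AnovaTable:
    """Split-plot ANOVA on a complete subjects x within-levels matrix.

    ``values[i, j]`` is subject *i* at within-level *j*; ``between[i]`` is the
    subject's group.  Requires >= 2 subjects per group and no missing cells.
    Zero-variance error strata yield NaN F values flagged in ``warnings``
    rather than division errors.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise DesignError("values must be a 2-D matrix with >= 2 within levels")
    if np.isnan(y).any():
        raise DesignError("missing cells are not allowed in the split-plot design")
    groups = np.asarray(between)
    if groups.shape[0] != y.shape[0]:
        raise DesignError("between labels must match the number of subjects")
    levels = sorted(set(groups.tolist()))
    if len(levels) < 2:
        raise DesignError(f"between factor needs >= 2 levels, got {levels}")
    for lev in levels:
        if (groups == lev).sum() < 2:
            raise DesignError(f"group {lev!r} has fewer than 2 subjects")

    n, k = y.shape
    g = len(levels)
    gm = y.mean()
    subj_means = y.mean(axis=1)
    col_means = y.mean(axis=0)

    ss_total = float(((y - gm) ** 2).sum())
    ss_between_subj = float(k * ((subj_means - gm) ** 2).sum())

    ss_a = 0.0
    ss_int = 0.0
    for lev in levels:
        mask = groups == lev
        n_g = int(mask.sum())
        g_mean = y[mask].mean()
        ss_a += k * n_g * (g_mean - gm) ** 2
        cell = y[mask].mean(axis=0)  # group x within-level means
        ss_int += n_g * ((cell - g_mean - col_means + gm) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_a
    ss_w = float(n * ((col_means - gm) ** 2).sum())
    ss_err = ss_total - ss_a - ss_subj_within - ss_w - ss_int
    ss_err = max(ss_err, 0.0)

    df_a, df_s = g - 1, n - g
    df_w, df_int, df_err = k - 1, (g - 1) * (k - 1), (n - g) * (k - 1)
    ms_s = ss_subj_within / df_s if df_s > 0 else float("nan")
    ms_err = ss_err / df_err if df_err > 0 else float("nan")

    warnings: list[str] = []
    if ss_total == 0:
        warnings.append("zero total variance: all F undefined")
    if ms_s == 0:
        warnings.append("zero-variance between-subjects error stratum")
    if ms_err == 0:
        warnings.append("zero-variance within-subjects error stratum")

    eps = _gg_epsilon(y) if gg_correction else 1.0

    def row(name, ss, df, ms_e, df_e, err_name, corrected=False) -> EffectRow:
        f, p = _f_and_p(ss, df, ms_e, df_e)
        if corrected and np.isfinite(f):
            p = float(stats.f.sf(f, eps * df, eps * df_e))
        e, lab = eta_squared(min(ss, ss_total), ss_total)
        ss_e_total = ms_e * df_e if np.isfinite(ms_e) else float("nan")
        pe = ss / (ss + ss_e_total) if ss + ss_e_total > 0 else float("nan")
        return EffectRow(
            name=name, ss=ss, df=df, ms=ss / df if df else float("nan"),
            f=f, p=p, eta_sq=e, eta_label=lab, partial_eta_sq=pe,
            error_term=err_name,
        )

    subj_name = f"subjects within {between_name}"
    err_name = f"{within_name} x {subj_name}"
    effects = [
        row(between_name, ss_a, df_a, ms_s, df_s, subj_name),
        row(within_name, ss_w, df_w, ms_err, df_err, err_name,
            corrected=gg_correction),
        row(f"{within_name} x {between_name}", ss_int, df_int, ms_err, df_err,
            err_name, corrected=gg_correction),
    ]
    error_terms = [
        EffectRow(subj_name, ss_subj_within, df_s,
                  ms_s, float("nan"), float("nan"), float("nan"), "", error_term=""),
        EffectRow(err_name, ss_err, df_err,
                  ms_err, float("nan"), float("nan"), float("nan"), "",
                  error_term=""),
    ]
    return AnovaTable(
        design=f"split-plot {within_name} x {between_name}",
        effects=effects,
        error_terms=error_terms,
        total_ss=ss_total,
        total_df=n * k - 1,
        n_subjects=n,
        additive=True,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# two-way factorial ANOVA (Type III via effect coding)


def _effect_code(labels: np.ndarray, levels: list[str]) -> np.ndarray:
    """Sum-to-zero (deviation) coding: L-1 columns, last level coded -1."""
    cols = np.zeros((labels.size, len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[labels == lev, j] = 1.0
    cols[labels == levels[-1], :] = -1.0
    return cols


def _rss(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def twoway_anova(
    y: list[float] | np.ndarray,
    factor_a: list[str] | np.ndarray,
    factor_b: list[str] | np.ndarray,
    *,
    a_name: str = "A",
    b_name: str = "B",
) -> AnovaTable:
    """Two-way fixed-effects ANOVA with Type III sums of squares.

    Handles unbalanced cell counts; empty cells attach an estimability
    warning (the interaction df drops to the rank actually supported).
    Rows with a missing (NaN/None/'missing') level in either factor are the
    caller's responsibility to drop beforehand.
    """
    yv = np.asarray(y, dtype=float)
    a = np.asarray([str(v) for v in factor_a])
    b = np.asarray([str(v) for v in factor_b])
    if not (yv.size == a.size == b.size):
        raise DesignError("y, factor_a, factor_b must have equal length")
    if np.isnan(yv).any():
        raise DesignError("response contains missing values")
    a_levels = sorted(set(a.tolist()))
    b_levels = sorted(set(b.tolist()))
    if len(a_levels) < 2:
        raise DesignError(f"factor {a_name} has a single level: {a_levels}")
    if len(b_levels) < 2:
        raise DesignError(f"factor {b_name} has a single level: {b_levels}")

    warnings: list[str] = []
    occupied = {(la, lb) for la, lb in zip(a, b)}
    n_empty = len(a_levels) * len(b_levels) - len(occupied)
    if n_empty:
        warnings.append(
            f"{n_empty} empty cell(s): interaction not fully estimable"
        )

    n = yv.size
    intercept = np.ones((n, 1))
    xa = _effect_code(a, a_levels)
    xb = _effect_code(b, b_levels)
    xab = np.einsum("ni,nj->nij", xa, xb).reshape(n, -1)

    x_full = np.hstack([intercept, xa, xb, xab])
    rss_full, rank_full = _rss(x_full, yv)
    df_err = n - rank_full
    ss_err = rss_full
    ms_err = ss_err / df_err if df_err > 0 else float("nan")
    if df_err > 0 and ms_err == 0:
        warnings.append("zero residual variance: all F undefined")

    gm = yv.mean()
    ss_total = float(((yv - gm) ** 2).sum())

    def drop(cols_to_drop: np.ndarray) -> tuple[float, int]:
        keep = [intercept]
        for block in (xa, xb, xab):
            if block is not cols_to_drop:
                keep.append(block)
        rss_red, rank_red = _rss(np.hstack(keep), yv)
        return max(rss_red - rss_full, 0.0), rank_full - rank_red

    effects = []
    for name, block in (
        (a_name, xa),
        (b_name, xb),
        (f"{a_name} x {b_name}", xab),
    ):
        ss, df = drop(block)
        f, p = _f_and_p(ss, df, ms_err, df_err)
        e, lab = eta_squared(min(ss, ss_total), ss_total) if ss_total > 0 else (
            float("nan"), "undefined")
        pe = ss / (ss + ss_err) if ss + ss_err > 0 else float("nan")
        effects.append(
            EffectRow(
                name=name, ss=ss, df=df,
                ms=ss / df if df else float("nan"),
                f=f, p=p, eta_sq=e, eta_label=lab, partial_eta_sq=pe,
                error_term="residual",
            )
        )

    additive = bool(
        abs(sum(r.ss for r in effects) + ss_err - ss_total)
        <= 1e-8 * max(1.0, ss_total)
    )
    error_terms = [
        EffectRow("residual", ss_err, df_err, ms_err,
                  float("nan"), float("nan"), float("nan"), "", error_term="")
    ]
    return AnovaTable(
        design=f"two-way {a_name} x {b_name} (Type III)",
        effects=effects,
        error_terms=error_terms,
        total_ss=ss_total,
        total_df=n - 1,
        n_subjects=n,
        additive=additive,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# post-hoc pairwise comparisons


def _finish_comparisons(
    raw: list[tuple[str, str, float, float, float, float]],
    family: str,
    alpha: float,
) -> PosthocResult:
    p_adj = bonferroni([r[5] if np.isfinite(r[5]) else 1.0 for r in raw])
    comps = []
    for (la, lb, ma, mb, t, p), pa in zip(raw, p_adj):
        if not np.isfinite(p):
            pa = float("nan")
        comps.append(
            Comparison(
                level_a=la, level_b=lb, mean_a=ma, mean_b=mb,
                mean_diff=ma - mb, t=t, p_raw=p, p_adjusted=float(pa),
                significant=bool(np.isfinite(pa) and pa <= alpha),
            )
        )
    return PosthocResult(
        family=family, alpha=alpha, family_size=len(comps), comparisons=comps
    )


def _safe_ttest_ind(xa: np.ndarray, xb: np.ndarray) -> tuple[float, float]:
    if xa.size < 2 or xb.size < 2 or (xa.std() == 0 and xb.std() == 0):
        return float("nan"), float("nan")
    t, p = stats.ttest_ind(xa, xb, equal_var=True)
    return float(t), float(p)


def posthoc_pairwise_independent(
    values_by_level: dict[str, np.ndarray], alpha: float, family: str = ""
) -> PosthocResult:
    """All pairwise pooled-variance t-tests between independent groups,
    Bonferroni-adjusted over the C(L,2) family."""
    raw = []
    for la, lb in itertools.combinations(sorted(values_by_level), 2):
        xa = np.asarray(values_by_level[la], dtype=float)
        xb = np.asarray(values_by_level[lb], dtype=float)
        t, p = _safe_ttest_ind(xa, xb)
        raw.append((la, lb, float(xa.mean()), float(xb.mean()), t, p))
    return _finish_comparisons(raw, family, alpha)


def posthoc_pairwise_paired(
    matrix: np.ndarray, labels: list[str], alpha: float, family: str = ""
) -> PosthocResult:
    """All pairwise paired t-tests between the columns of a complete
    subjects x levels matrix, Bonferroni-adjusted."""
    y = np.asarray(matrix, dtype=float)
    raw = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        d = y[:, i] - y[:, j]
        if d.std() == 0:
            t, p = float("nan"), float("nan")
        else:
            t, p = stats.ttest_rel(y[:, i], y[:, j])
            t, p = float(t), float(p)
        raw.append(
            (labels[i], labels[j], float(y[:, i].mean()), float(y[:, j].mean()),
             t, p)
        )
    return _finish_comparisons(raw, family, alpha)


def posthoc_between_at_each_level(
    matrix: np.ndarray,
    between: np.ndarray,
    level_names: list[str],
    alpha: float,
    family: str = "",
) -> PosthocResult:
    """Two-group comparison at each within-level (e.g. men vs women at each
    checkpoint), Bonferroni family = number of levels.

    ``level_a``/``level_b`` are '<level>:<group>' strings; mean_diff is
    group_a minus group_b with groups in sorted order.
    """
    y = np.asarray(matrix, dtype=float)
    groups = np.asarray(between)
    g_levels = sorted(set(groups.tolist()))
    if len(g_levels) != 2:
        raise DesignError("per-level comparison requires exactly 2 groups")
    ga, gb = g_levels
    raw = []
    for j, name in enumerate(level_names):
        xa, xb = y[groups == ga, j], y[groups == gb, j]
        t, p = _safe_ttest_ind(xa, xb)
        raw.append(
            (f"{name}:{ga}", f"{name}:{gb}", float(xa.mean()), float(xb.mean()),
             t, p)
        )
    return _finish_comparisons(raw, family, alpha)
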