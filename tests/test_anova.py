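import itertools

import numpy as np
import pytest

import spartapace as sp
from spartapace.anova import (
    DesignError,
    effect_size_label,
    posthoc_pairwise_independent,
    posthoc_pairwise_paired,
)

# ---------------------------------------------------------------------------
# brute-force enumeration oracles: every SS by direct summation over its
# definition, independent of the engine's vectorised path


def split_plot_oracle(y, groups):
    n, k = y.shape
    levels = sorted(set(groups))
    gm = sum(y[i, j] for i in range(n) for j in range(k)) / (n * k)
    subj = [sum(y[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(y[i, j] for i in range(n)) / n for j in range(k)]
    gmean = {
        g: np.mean([y[i, j] for i in range(n) if groups[i] == g for j in range(k)])
        for g in levels
    }
    cell = {
        (g, j): np.mean([y[i, j] for i in range(n) if groups[i] == g])
        for g in levels
        for j in range(k)
    }
    ng = {g: sum(1 for gi in groups if gi == g) for g in levels}
    ss = {}
    ss["total"] = sum((y[i, j] - gm) ** 2 for i in range(n) for j in range(k))
    ss["A"] = sum(k * ng[g] * (gmean[g] - gm) ** 2 for g in levels)
    ss["subj_within"] = sum(
        k * (subj[i] - gmean[groups[i]]) ** 2 for i in range(n)
    )
    ss["W"] = sum(n * (col[j] - gm) ** 2 for j in range(k))
    ss["int"] = sum(
        ng[g] * (cell[(g, j)] - gmean[g] - col[j] + gm) ** 2
        for g in levels
        for j in range(k)
    )
    ss["err"] = sum(
        (y[i, j] - cell[(groups[i], j)] - subj[i] + gmean[groups[i]]) ** 2
        for i in range(n)
        for j in range(k)
    )
    return ss


def balanced_twoway_oracle(y, a, b):
    """Cell-mean formulas for a balanced design; equals Type III there."""
    a_levels, b_levels = sorted(set(a)), sorted(set(b))
    gm = np.mean(y)
    cells = {
        (la, lb): [yi for yi, ai, bi in zip(y, a, b) if (ai, bi) == (la, lb)]
        for la in a_levels
        for lb in b_levels
    }
    r = len(next(iter(cells.values())))
    assert all(len(c) == r for c in cells.values()), "oracle requires balance"
    amean = {la: np.mean([yi for yi, ai in zip(y, a) if ai == la]) for la in a_levels}
    bmean = {lb: np.mean([yi for yi, bi in zip(y, b) if bi == lb]) for lb in b_levels}
    ss = {}
    ss["A"] = len(b_levels) * r * sum((amean[la] - gm) ** 2 for la in a_levels)
    ss["B"] = len(a_levels) * r * sum((bmean[lb] - gm) ** 2 for lb in b_levels)
    ss["AB"] = r * sum(
        (np.mean(cells[(la, lb)]) - amean[la] - bmean[lb] + gm) ** 2
        for la in a_levels
        for lb in b_levels
    )
    ss["err"] = sum(
        (yi - np.mean(cells[(la, lb)])) ** 2
        for la in a_levels
        for lb in b_levels
        for yi in cells[(la, lb)]
    )
    ss["total"] = sum((yi - gm) ** 2 for yi in y)
    return ss


# ---------------------------------------------------------------------------


class TestMixedAnova:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for nM, nF, k in ((3, 2, 4), (4, 4, 3), (6, 3, 5)):
            y = rng.normal(size=(nM + nF, k))
            groups = np.array(["M"] * nM + ["F"] * nF)
            tab = sp.mixed_anova(y, groups)
            oracle = split_plot_oracle(y, groups)
            tol = 1e-8 * max(1.0, oracle["total"])
            assert abs(tab.effect("sex").ss - oracle["A"]) < tol
            assert abs(tab.effect("checkpoint").ss - oracle["W"]) < tol
            assert abs(tab.effect("checkpoint x sex").ss - oracle["int"]) < tol
            assert abs(tab.error_terms[0].ss - oracle["subj_within"]) < tol
            assert abs(tab.error_terms[1].ss - oracle["err"]) < tol
            assert abs(tab.total_ss - oracle["total"]) < tol

    def test_checkpoint_only_effect(self):
        # two sexes x two runners x two checkpoints; every subject runs the
        # same (0, 1) pattern plus a subject offset: sex and interaction SS
        # vanish, the within effect carries the structure
        y = np.array([[0.0, 1.0], [0.2, 1.2], [0.0, 1.0], [0.2, 1.2]])
        groups = np.array(["M", "M", "F", "F"])
        tab = sp.mixed_anova(y, groups)
        oracle = split_plot_oracle(y, groups)
        assert tab.effect("sex").ss == pytest.approx(0.0, abs=1e-12)
        assert tab.effect("checkpoint").ss == pytest.approx(oracle["W"])
        assert tab.effect("checkpoint").ss > 0
        assert tab.effect("checkpoint x sex").ss == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_flags_not_crashes(self):
        y = np.full((6, 4), 3.14)
        tab = sp.mixed_anova(y, np.array(["M", "M", "M", "F", "F", "F"]))
        assert tab.total_ss == 0
        assert all(not np.isfinite(e.f) for e in tab.effects)
        assert tab.warnings

    def test_ss_additivity_shift_and_scale_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n, k = int(rng.integers(4, 12)), int(rng.integers(2, 6))
            y = rng.normal(size=(n, k))
            groups = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
            tab = sp.mixed_anova(y, groups)
            parts = sum(e.ss for e in tab.effects) + sum(
                e.ss for e in tab.error_terms
            )
            assert parts == pytest.approx(tab.total_ss, rel=1e-8)
            shifted = sp.mixed_anova(y + 7.5, groups)
            scaled = sp.mixed_anova(y * 3.25, groups)
            for eff in ("sex", "checkpoint", "checkpoint x sex"):
                f0 = tab.effect(eff).f
                assert shifted.effect(eff).f == pytest.approx(f0, rel=1e-9)
                assert scaled.effect(eff).f == pytest.approx(f0, rel=1e-9)

    def test_design_errors(self):
        y = np.zeros((3, 4))
        with pytest.raises(DesignError):
            sp.mixed_anova(y, np.array(["M", "M", "F"]))  # F has 1 subject
        y2 = np.zeros((4, 4))
        y2[0, 0] = np.nan
        with pytest.raises(DesignError):
            sp.mixed_anova(y2, np.array(["M", "M", "F", "F"]))


class TestTwowayAnova:
    def test_balanced_equal_cell_means_gives_zero_f(self):
        y = np.array([1.0, 1.1, 0.9, 1.0, 1.1, 0.9, 1.0, 1.1, 0.9, 1.0, 1.1, 0.9])
        a = np.array(["a"] * 6 + ["b"] * 6)
        b = np.tile(["x"] * 3 + ["y"] * 3, 2)
        tab = sp.twoway_anova(y, a, b)
        for eff in tab.effects:
            assert eff.ss == pytest.approx(0.0, abs=1e-12)

    def test_pure_factor_a_effect_matches_oracle(self):
        # cell means (0,0 / 10,10) along A: all between-cell SS belongs to A
        y = np.array([0, 0, 0, 0, 10, 10, 10, 10], dtype=float)
        y += np.array([-0.1, 0.1, -0.1, 0.1, -0.1, 0.1, -0.1, 0.1])
        a = np.array(["a1"] * 4 + ["a2"] * 4)
        b = np.tile(["b1", "b1", "b2", "b2"], 2)
        tab = sp.twoway_anova(y, a, b, a_name="A", b_name="B")
        oracle = balanced_twoway_oracle(y, a, b)
        assert tab.effect("A").ss == pytest.approx(oracle["A"])
        assert tab.effect("B").ss == pytest.approx(0.0, abs=1e-10)
        assert tab.effect("A x B").ss == pytest.approx(0.0, abs=1e-10)
        assert tab.error_terms[0].ss == pytest.approx(oracle["err"])

    def test_balanced_random_matches_oracle_and_is_additive(self):
        rng = np.random.default_rng(5)
        for na, nb, r in ((2, 2, 3), (3, 2, 4), (3, 4, 5)):
            a = np.repeat([f"a{i}" for i in range(na)], nb * r)
            b = np.tile(np.repeat([f"b{i}" for i in range(nb)], r), na)
            y = rng.normal(size=na * nb * r)
            tab = sp.twoway_anova(y, a, b, a_name="A", b_name="B")
            oracle = balanced_twoway_oracle(y, a, b)
            tol = 1e-8 * max(1.0, oracle["total"])
            assert abs(tab.effect("A").ss - oracle["A"]) < tol
            assert abs(tab.effect("B").ss - oracle["B"]) < tol
            assert abs(tab.effect("A x B").ss - oracle["AB"]) < tol
            assert abs(tab.error_terms[0].ss - oracle["err"]) < tol
            assert tab.additive

    def test_unbalanced_type_iii_matches_statsmodels(self):
        import pandas as pd
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(7)
        n = 80
        a = rng.choice(["a1", "a2", "a3"], n, p=[0.5, 0.3, 0.2])
        b = rng.choice(["b1", "b2"], n, p=[0.7, 0.3])
        y = rng.normal(size=n) + (a == "a2") * 0.5 + (b == "b2") * 0.3
        tab = sp.twoway_anova(y, a, b, a_name="A", b_name="B")
        fit = smf.ols(
            "y ~ C(a, Sum)*C(b, Sum)", pd.DataFrame({"y": y, "a": a, "b": b})
        ).fit()
        ref = anova_lm(fit, typ=3)
        pairs = (
            ("A", "C(a, Sum)"),
            ("B", "C(b, Sum)"),
            ("A x B", "C(a, Sum):C(b, Sum)"),
        )
        for eff, src in pairs:
            assert tab.effect(eff).ss == pytest.approx(
                ref.loc[src, "sum_sq"], rel=1e-8
            )
            assert tab.effect(eff).f == pytest.approx(ref.loc[src, "F"], rel=1e-8)
        assert tab.error_terms[0].ss == pytest.approx(
            ref.loc["Residual", "sum_sq"], rel=1e-8
        )

    def test_empty_cell_warns(self):
        y = np.arange(6, dtype=float)
        a = np.array(["a1", "a1", "a1", "a2", "a2", "a2"])
        b = np.array(["b1", "b2", "b1", "b1", "b1", "b1"])  # (a2,b2) empty
        tab = sp.twoway_anova(y, a, b)
        assert any("empty cell" in w for w in tab.warnings)

    def test_single_level_rejected(self):
        with pytest.raises(DesignError):
            sp.twoway_anova([1.0, 2.0], ["a", "a"], ["x", "y"])


class TestBonferroniAndEta:
    def test_bonferroni_examples(self):
        assert sp.bonferroni([0.01] * 45)[0] == pytest.approx(0.45)
        assert sp.bonferroni([0.5, 0.5, 0.5]).tolist() == [1.0, 1.0, 1.0]
        assert sp.bonferroni([0.2]).tolist() == [0.2]

    def test_bonferroni_domain(self):
        with pytest.raises(ValueError):
            sp.bonferroni([1.2])

    @pytest.mark.parametrize(
        "value,label",
        [
            (0.54, "large"), (0.14, "large"), (0.06, "medium"),
            (0.01, "small"), (0.005, "negligible"),
        ],
    )
    def test_eta_labels(self, value, label):
        got, lab = sp.eta_squared(value * 100, 100.0)
        assert got == pytest.approx(value)
        assert lab == label
        assert effect_size_label(value) == label

    def test_eta_zero_total_flagged(self):
        val, lab = sp.eta_squared(0.0, 0.0)
        assert np.isnan(val) and lab == "undefined"

    def test_eta_domain(self):
        with pytest.raises(ValueError):
            sp.eta_squared(2.0, 1.0)


class TestKSNormality:
    def test_calibration_on_normal_and_exponential(self):
        hits_norm = hits_exp = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            if sp.ks_normality(rng.normal(size=1000)).p > 0.05:
                hits_norm += 1
            if sp.ks_normality(rng.exponential(size=1000)).p < 0.05:
                hits_exp += 1
        assert hits_norm >= 18
        assert hits_exp >= 18

    def test_degenerate_and_domain(self):
        res = sp.ks_normality([2.0] * 10)
        assert res.degenerate
        with pytest.raises(ValueError):
            sp.ks_normality([1.0, 2.0])


class TestPosthocHelpers:
    def test_paired_and_independent_agree_with_bonferroni_identity(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(30, 3)) + np.array([0.0, 0.5, 2.0])
        ph = posthoc_pairwise_paired(y, ["c1", "c2", "c3"], alpha=0.05)
        assert ph.family_size == 3
        for c in ph.comparisons:
            assert c.p_adjusted == pytest.approx(min(1.0, c.p_raw * 3))
            assert c.significant == (c.p_adjusted <= 0.05)
        big = ph.get("c1", "c3")
        assert big.significant and abs(big.mean_diff) > 1.5
        groups = {"g1": rng.normal(size=40), "g2": rng.normal(size=40) + 3.0}
        ph2 = posthoc_pairwise_independent(groups, alpha=0.05)
        assert ph2.comparisons[0].significant
        assert ph2.comparisons[0].mean_diff == pytest.approx(
            groups["g1"].mean() - groups["g2"].mean()
        )
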