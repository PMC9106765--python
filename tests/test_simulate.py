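import dataclasses

import numpy as np
import pytest

import spartapace as sp
from spartapace import reference as ref
from spartapace.simulate import SimulationConfig


class TestDefaultConfig:
    def test_calibration_for_bundled_course(self, spartathlon):
        cfg = sp.default_config(spartathlon)
        assert cfg.mean_speed_by_sex == (2.22, 2.21)
        assert cfg.speed_sd_by_sex == (0.32, 0.28)
        assert cfg.sex_fraction_male == pytest.approx(0.868)
        # profile minimum at checkpoint 7 (the climb to the Sangas pass)
        assert int(np.argmin(cfg.base_profile)) + 1 == 7
        # multipliers are the published men's means over the men's average
        assert np.allclose(
            cfg.base_profile,
            np.array(ref.CHECKPOINT_SPEED_MEAN["M"]) / 2.22,
        )
        # men start relatively faster (positive shift at cp1-2)
        assert cfg.sex_ccs_shift[0] > 0 and cfg.sex_ccs_shift[1] > 0
        # age weights follow the published cohort distribution
        assert cfg.age_distribution["40-44"] == pytest.approx(629 / 2598)
        assert sum(cfg.age_distribution.values()) == pytest.approx(1.0)

    def test_flat_fallback_for_other_courses(self, flat_course):
        cfg = sp.default_config(flat_course)
        assert set(cfg.base_profile) == {1.0}
        assert set(cfg.sex_ccs_shift) == {0.0}
        assert cfg.amplitude_curve == (1.0, 0.0, 0.0)

    def test_config_json_round_trip(self, spartathlon, tmp_path):
        cfg = sp.default_config(spartathlon, n_runners=123, seed=9)
        path = tmp_path / "sim.json"
        cfg.to_json(path)
        assert SimulationConfig.from_json(path) == cfg

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_runners=0, base_profile=(1.0,), sex_ccs_shift=(0.0,))
        with pytest.raises(ValueError):
            SimulationConfig(
                n_runners=5, base_profile=(1.0, -1.0), sex_ccs_shift=(0.0, 0.0)
            )
        with pytest.raises(ValueError):
            SimulationConfig(
                n_runners=5, base_profile=(1.0,), sex_ccs_shift=(0.0, 0.0)
            )


class TestGenerate:
    def test_fixed_seed_is_byte_identical(self, spartathlon, tmp_path):
        cfg = sp.default_config(spartathlon, n_runners=150, seed=5)
        paths = []
        for name in ("a.csv", "b.csv"):
            cohort, _ = sp.generate(cfg, spartathlon)
            path = tmp_path / name
            sp.write_splits(path, cohort)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_zero_noise_reproduces_profile_accs(self, spartathlon):
        """With no noise, no sex shift and unit amplitude, every runner runs
        the configured profile exactly, so ACCS equals the profile-level
        ACCS (independent of drawn speed) up to 1 s rounding.

        The self-consistent profile ACCS normalises by the harmonic
        (time-weighted) average the profile itself implies; it is 17.14 %,
        a shade under the 17.30 % obtained when normalising by the published
        cohort average 2.22 m/s, because the published per-checkpoint means
        and the published average speed are each rounded independently."""
        cfg = dataclasses.replace(
            sp.default_config(spartathlon, n_runners=40, seed=1),
            sex_ccs_shift=tuple([0.0] * 10),
            variability_curve=(0.0, 0.0, 0.0),
            amplitude_curve=(1.0, 0.0, 0.0),
        )
        m = np.array(cfg.base_profile)
        d = spartathlon.segment_m_array
        vbar = d.sum() / (d / m).sum()  # harmonic profile average (multiplier)
        expected = np.mean(np.abs(100.0 * (m - vbar) / vbar))
        assert expected == pytest.approx(17.14, abs=0.05)
        assert abs(expected - 17.2973) < 0.25
        cohort, _ = sp.generate(cfg, spartathlon)
        metrics = sp.cohort_metrics(cohort)
        assert np.allclose(metrics["accs"], expected, atol=0.1)

    def test_generated_records_validate_cleanly(self, small_cohort, tmp_path):
        cohort, _ = small_cohort
        path = tmp_path / "sim.csv"
        sp.write_splits(path, cohort)
        reread, report = sp.load_splits(path, cohort.course)
        assert report.n_excluded == 0
        assert len(reread) == len(cohort)
        limit = cohort.course.time_limit_s
        assert all(r.cumulative_s[-1] <= limit for r in reread.records)

    def test_default_calibration_structure(self, spartathlon):
        cfg = sp.default_config(spartathlon, n_runners=2000, seed=42)
        cohort, meta = sp.generate(cfg, spartathlon)
        male_frac = (cohort.sexes() == "M").mean()
        assert abs(male_frac - 0.868) < 0.02
        metrics = sp.cohort_metrics(cohort)
        cp_cols = [f"cp{j}_speed" for j in range(1, 11)]
        mean_profile = metrics[cp_cols].mean(axis=0).to_numpy()
        shape = sp.classify_shape(mean_profile)
        assert shape.label == "reverse_j"
        assert shape.minimum_checkpoint == 7
        # male cohort mean speeds track the per-runner configured profile
        # (drawn speed x amplitude-exponentiated multipliers) closely
        m = np.array(cfg.base_profile)
        male = metrics["sex"].to_numpy() == "M"
        gamma = meta.runners["amplitude"].to_numpy()[male]
        drawn = meta.runners["drawn_speed_ms"].to_numpy()[male]
        expected = (
            drawn[:, None] * np.exp(gamma[:, None] * np.log(m)[None, :])
        ).mean(axis=0)
        observed = metrics.loc[male, cp_cols].mean(axis=0).to_numpy()
        assert np.all(np.abs(observed - expected) < 0.05)

    def test_noise_free_ccs_matches_configured_profile(self, spartathlon):
        """Generator consistency with the metric definitions: as noise -> 0,
        per-runner signed CCS converges to the configured profile's CCS."""
        cfg = dataclasses.replace(
            sp.default_config(spartathlon, n_runners=20, seed=3),
            sex_ccs_shift=tuple([0.0] * 10),
            variability_curve=(0.0, 0.0, 0.0),
            amplitude_curve=(1.0, 0.0, 0.0),
        )
        cohort, _ = sp.generate(cfg, spartathlon)
        metrics = sp.cohort_metrics(cohort)
        m = np.array(cfg.base_profile)
        seg = cohort.course.segment_m_array
        vbar_mult = cohort.course.total_m / (seg / m).sum()
        expected_ccs = 100.0 * (m - vbar_mult) / vbar_mult
        got = metrics[[f"cp{j}_ccs_signed" for j in range(1, 11)]].to_numpy()
        assert np.allclose(got, expected_ccs[None, :], atol=0.15)

    def test_profile_length_mismatch_rejected(self, flat_course):
        cfg = sp.default_config(flat_course, n_runners=10)
        short = sp.course_from_segments("s", [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            sp.generate(cfg, short)


class TestRecoveryExperiment:
    def test_single_replicate_rates_are_binary(self, spartathlon):
        cfg = sp.default_config(spartathlon, n_runners=400, seed=11)
        rep = sp.recovery_experiment(cfg, spartathlon, 1)
        assert rep.n_replicates == 1
        assert set(rep.rates.values()) <= {0.0, 1.0}

    def test_replicates_vary_by_seed(self, spartathlon):
        cfg = sp.default_config(spartathlon, n_runners=300, seed=11)
        rep = sp.recovery_experiment(cfg, spartathlon, 2, base_seed=50)
        cohort_a, _ = sp.generate(dataclasses.replace(cfg, seed=50), spartathlon)
        cohort_b, _ = sp.generate(dataclasses.replace(cfg, seed=51), spartathlon)
        assert cohort_a.records[0].cumulative_s != cohort_b.records[0].cumulative_s
        assert len(rep.records) == 2

    def test_invalid_replicate_count(self, spartathlon):
        cfg = sp.default_config(spartathlon, n_runners=10)
        with pytest.raises(ValueError):
            sp.recovery_experiment(cfg, spartathlon, 0)
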