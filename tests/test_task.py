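"""Task generator: reward calibration, schedule invariants, agent simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rpeadapt as ra
from rpeadapt.task import _calibrate_gaussian, _discrete_moments


class TestRewardDistribution:
    def test_draws_are_bounded_integers(self):
        rng = np.random.default_rng(1)
        d = ra.RewardDistribution(35, 15)
        x = ra.draw_rewards(d, 5000, rng)
        assert x.dtype.kind == "i"
        assert x.min() >= 0 and x.max() <= 100

    @pytest.mark.parametrize("mean,sd", [(35, 5), (65, 10), (35, 15), (65, 15)])
    def test_population_moments_are_calibrated_exactly(self, mean, sd):
        # oracle: exact moments of the discrete round-then-truncate pmf
        mu, sigma = _calibrate_gaussian(float(mean), float(sd), 0.0, 100.0)
        m, s = _discrete_moments(mu, sigma, np.arange(0, 101, dtype=float))
        assert m == pytest.approx(mean, abs=1e-6)
        assert s == pytest.approx(sd, abs=1e-6)

    def test_sample_moments_converge(self):
        rng = np.random.default_rng(2)
        x = ra.draw_rewards(ra.RewardDistribution(35, 15), 10_000, rng)
        assert abs(float(x.mean()) - 35) < 0.4
        assert abs(float(x.std(ddof=1)) - 15) < 0.2

    def test_degenerate_zero_variance(self):
        rng = np.random.default_rng(3)
        assert all(ra.draw_reward(ra.RewardDistribution(65, 0), rng) == 65
                   for _ in range(20))

    def test_mean_outside_scale_rejected(self):
        with pytest.raises(ra.ConfigError):
            ra.RewardDistribution(120, 5)


class TestSchedule:
    def test_canonical_invariants(self, canonical_config):
        rng = np.random.default_rng(10)
        sched = ra.build_schedule(canonical_config, rng)
        assert len(sched.conditions) == 6
        # each SD appears twice, once per EV
        seen = {(c.sd, c.ev) for c in sched.conditions}
        assert seen == {(sd, ev) for sd in (5.0, 10.0, 15.0)
                        for ev in (35.0, 65.0)}
        # block lengths within range, per-condition trials conserved
        totals = {}
        for session in sched.blocks:
            for cid, length in session:
                assert 4 <= length <= 6
                totals[cid] = totals.get(cid, 0) + length
        assert all(t == canonical_config.trials_per_condition
                   for t in totals.values())
        # exact control fraction
        n_ctrl = sum(len(v) for v in sched.control_trials.values())
        assert n_ctrl / sched.n_trials == pytest.approx(0.2)

    def test_blocks_alternate_conditions(self, canonical_config):
        rng = np.random.default_rng(11)
        sched = ra.build_schedule(canonical_config, rng)
        for session in sched.blocks:
            cids = [cid for cid, _ in session]
            assert all(a != b for a, b in zip(cids, cids[1:]))

    def test_indivisible_control_fraction_rejected(self):
        with pytest.raises(ra.ConfigError, match="control fraction"):
            ra.TaskConfig(trials_per_condition=21, control_fraction=0.2)

    def test_bad_session_pairing_rejected(self):
        with pytest.raises(ra.ConfigError):
            ra.TaskConfig(session_sd_pairs=((5.0, 10.0), (10.0, 15.0),
                                            (10.0, 15.0)))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_invariants_hold_for_any_seed(self, seed):
        cfg = ra.TaskConfig()
        sched = ra.build_schedule(cfg, np.random.default_rng(seed))
        assert len(sched.conditions) == 6
        n_ctrl = sum(len(v) for v in sched.control_trials.values())
        assert n_ctrl / sched.n_trials == pytest.approx(0.2)
        trials = list(sched.trial_sequence())
        assert len(trials) == sched.n_trials


class TestSimulateAgent:
    def test_zero_learning_rate_never_updates(self, canonical_config):
        rng = np.random.default_rng(20)
        sched = ra.build_schedule(canonical_config, rng)
        params = ra.ModelParams(alpha=0.0, sigma_hat_sq=1e-3)
        df = ra.simulate_agent("rw", params, sched, rng)
        # noiseless-in-practice agent stays at the initial prediction
        assert np.allclose(df["prediction"], 50.0, atol=0.5)

    def test_full_learning_rate_tracks_previous_reward(self, canonical_config):
        rng = np.random.default_rng(21)
        sched = ra.build_schedule(canonical_config, rng)
        params = ra.ModelParams(alpha=1.0, sigma_hat_sq=1e-3)
        df = ra.simulate_agent("rw", params, sched, rng)
        for _, g in df.groupby("condition_id"):
            g = g.sort_values("trial_in_condition")
            assert np.allclose(g["prediction"].to_numpy()[1:],
                               g["reward"].to_numpy()[:-1], atol=0.5)

    def test_rpe_consistency_and_payoffs(self, aph_subject):
        df, _ = aph_subject
        live = ~df["missed"]
        assert np.allclose(df.loc[live, "rpe"],
                           df.loc[live, "reward"] - df.loc[live, "prediction"])
        main = live & ~df["is_control"]
        assert np.allclose(df.loc[main, "payoff"], df.loc[main, "reward"] / 10)
        assert df["prediction"].dropna().between(0, 100).all()

    def test_rpe_spread_orders_with_condition_sd(self, canonical_config):
        # oracle: empirical SD of delta over >= 1000 trials per SD level
        rng = np.random.default_rng(22)
        params = ra.ModelParams(alpha=0.6, gamma=0.5, C=0.05, sigma_hat_sq=25.0)
        frames = []
        for _ in range(10):
            sched = ra.build_schedule(canonical_config, rng)
            frames.append(ra.simulate_agent("ph", params, sched, rng))
        df = pd.concat(frames)
        spread = df.groupby("sd")["rpe"].std()
        assert spread[5.0] < spread[10.0] < spread[15.0]

    def test_unknown_model_rejected(self, canonical_config):
        rng = np.random.default_rng(23)
        sched = ra.build_schedule(canonical_config, rng)
        with pytest.raises(ValueError, match="unknown model"):
            ra.simulate_agent("qlearn", ra.ModelParams(), sched, rng)


class TestCohort:
    def test_determinism(self, canonical_config):
        sampler = ra.cohort_param_sampler("aph")
        a, _ = ra.simulate_cohort(2, "aph", sampler, canonical_config,
                                  np.random.default_rng(55))
        b, _ = ra.simulate_cohort(2, "aph", sampler, canonical_config,
                                  np.random.default_rng(55))
        pd.testing.assert_frame_equal(a, b)

    def test_truth_bookkeeping_and_structure(self, small_cohort):
        trials, truth = small_cohort
        assert sorted(trials["subject"].unique()) == sorted(truth)
        for s, params in truth.items():
            assert 0.0 <= params.nu <= 1.0
            assert trials[trials.subject == s]["condition_id"].nunique() == 6

    def test_rejects_empty_cohort(self, canonical_config):
        with pytest.raises(ra.ConfigError):
            ra.simulate_cohort(0, "rw", ra.cohort_param_sampler("rw"),
                               canonical_config, np.random.default_rng(0))

    def test_csv_roundtrip(self, small_cohort, tmp_path):
        trials, truth = small_cohort
        ra.write_trials(trials, tmp_path / "t.csv")
        back = ra.read_trials(tmp_path / "t.csv")
        pd.testing.assert_frame_equal(back, trials[list(ra.TRIAL_COLUMNS)],
                                      check_dtype=False)
        ra.write_truth(truth, tmp_path / "truth.json")
        loaded = ra.read_truth(tmp_path / "truth.json")
        assert loaded[0]["nu"] == pytest.approx(truth[0].nu)
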