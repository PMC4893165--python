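"""Learning rules: gains, recursions, limits and reductions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rpeadapt as ra
from rpeadapt.models import DEFAULT_D


class TestBayesGain:
    def test_equal_variances_give_half(self):
        k, _ = ra.bayes_gain(100.0, 100.0)
        assert k == pytest.approx(0.5)

    def test_uninformative_prior_limit(self):
        k, _ = ra.bayes_gain(1e12 * 100.0, 100.0)
        assert k == pytest.approx(1.0, abs=1e-9)

    def test_recursion_matches_conjugate_closed_form(self):
        # oracle: posterior variance of a conjugate-Gaussian mean after n
        # observations is sigma^2 * sigma0^2 / (sigma^2 + n * sigma0^2)
        sigma0_sq, sigma_sq = 400.0, 225.0
        pv = sigma0_sq
        for n in range(1, 51):
            _, pv = ra.bayes_gain(pv, sigma_sq)
            expected = sigma_sq * sigma0_sq / (sigma_sq + n * sigma0_sq)
            assert pv == pytest.approx(expected, rel=1e-12)

    def test_posterior_variance_strictly_decreases_and_gain_vanishes(self):
        pv = 500.0
        gains = []
        for _ in range(200):
            k, new_pv = ra.bayes_gain(pv, 100.0)
            assert new_pv < pv
            gains.append(k)
            pv = new_pv
        assert gains[-1] < 0.01

    def test_rejects_nonpositive_variance(self):
        with pytest.raises(ValueError):
            ra.bayes_gain(0.0, 100.0)


class TestGains:
    def test_rw_gain_constant(self):
        p = ra.ModelParams(alpha=0.3)
        assert all(ra.rw_gain(p) == 0.3 for _ in range(5))

    def test_ph_hand_unrolled_value(self):
        # gamma=0.5, C=0.05, k0=0.6, |delta|=10 -> 0.5*0.5 + 0.5*0.6 = 0.55
        p = ra.ModelParams(gamma=0.5, C=0.05)
        assert ra.ph_gain(0.6, 10.0, p) == pytest.approx(0.55)

    def test_ph_full_decay_limit(self):
        p = ra.ModelParams(gamma=1.0, C=1.0)
        assert ra.ph_gain(0.9, 0.4, p) == pytest.approx(0.4)
        assert ra.ph_gain(0.9, 50.0, p) == 1.0  # clipped

    def test_ph_rejects_negative_rpe_magnitude(self):
        with pytest.raises(ValueError):
            ra.ph_gain(0.5, -1.0, ra.ModelParams())

    def test_dual_gain_sign_routing(self):
        p = ra.ModelParams(alpha_pos=0.2, alpha_neg=0.5)
        assert ra.rw_dual_gain(3.0, p) == 0.2
        assert ra.rw_dual_gain(-3.0, p) == 0.5
        assert ra.rw_dual_gain(0.0, p) == 0.2  # zero goes positive

    def test_dual_step_arithmetic(self):
        p = ra.ModelParams(alpha_pos=0.2, alpha_neg=0.5)
        state = ra.init_state("rw_dual", p, y0=50.0)
        new_y, gain = ra.rw_dual_step(state, 40.0, p)  # delta = -10
        assert gain == 0.5
        assert new_y == pytest.approx(45.0)

    def test_dual_alternating_sequence_tracks_losses_only(self):
        # oracle: hand step-through with alpha+=0, alpha-=1 over 6 trials
        p = ra.ModelParams(alpha_pos=0.0, alpha_neg=1.0)
        state = ra.init_state("rw_dual", p, y0=50.0)
        rewards = [60.0, 40.0, 70.0, 30.0, 55.0, 20.0]
        expected_y = [50.0, 40.0, 40.0, 30.0, 30.0, 20.0]
        for r, exp in zip(rewards, expected_y):
            state = ra.advance("rw_dual", p, state, state.y, r)
            assert state.y == pytest.approx(exp)


class TestOmega:
    def test_anchor_at_smallest_sd(self):
        assert ra.omega(5.0, nu=1.0) == pytest.approx(1.0)

    def test_no_adaptation(self):
        assert ra.omega(15.0, nu=0.0) == pytest.approx(1.0)

    def test_full_adaptation_at_sd15(self):
        w = ra.omega(15.0, nu=1.0)
        assert w == pytest.approx(math.log(15) / math.log(5), rel=1e-12)
        assert 1.0 / w == pytest.approx(0.595, abs=1e-3)

    def test_omega_positive_guard(self):
        with pytest.raises(ValueError, match="omega"):
            ra.omega(1.0, nu=1.0)  # log(1) = 0 -> omega = 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(nu=st.floats(0.01, 1.0), k=st.floats(0.0, 1.0),
           delta=st.floats(-50.0, 50.0))
    def test_effective_update_shrinks_with_sd(self, nu, k, delta):
        updates = [abs(k * delta / ra.omega(sd, nu)) for sd in (5.0, 10.0, 15.0)]
        assert updates[0] >= updates[1] >= updates[2]


def _simulate_sequence(model, params, rewards, sd=10.0, y0=50.0):
    state = ra.init_state(model, params, y0=y0)
    ys = []
    for r in rewards:
        state = ra.advance(model, params, state, state.y, r, sd=sd)
        ys.append(state.y)
    return np.array(ys)


class TestReductions:
    REWARDS = list(np.random.default_rng(7).integers(10, 90, size=40).astype(float))

    @pytest.mark.parametrize("sd", [5.0, 10.0, 15.0])
    def test_adaptive_ph_with_zero_nu_is_plain_ph(self, sd):
        p = ra.ModelParams(alpha=0.4, gamma=0.6, C=0.05, nu=0.0)
        a = _simulate_sequence("aph", p, self.REWARDS, sd=sd)
        b = _simulate_sequence("ph", p, self.REWARDS, sd=sd)
        np.testing.assert_array_equal(a, b)

    def test_ph_with_zero_gamma_is_rw(self):
        p = ra.ModelParams(alpha=0.35, gamma=0.0, C=0.1)
        a = _simulate_sequence("ph", p, self.REWARDS)
        b = _simulate_sequence("rw", p, self.REWARDS)
        np.testing.assert_array_equal(a, b)

    def test_dual_with_equal_rates_is_rw(self):
        p = ra.ModelParams(alpha=0.35, alpha_pos=0.35, alpha_neg=0.35)
        a = _simulate_sequence("rw_dual", p, self.REWARDS)
        b = _simulate_sequence("rw", p, self.REWARDS)
        np.testing.assert_array_equal(a, b)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(alpha=st.floats(0, 1), gamma=st.floats(0, 1),
           C=st.floats(1e-4, 0.2), nu=st.floats(0, 1),
           seed=st.integers(0, 10_000))
    def test_gains_clipped_and_predictions_finite(self, alpha, gamma, C, nu,
                                                  seed):
        p = ra.ModelParams(alpha=alpha, gamma=gamma, C=C, nu=nu)
        rewards = np.random.default_rng(seed).integers(0, 101, 30).astype(float)
        for model in ("rw", "ph", "aph", "rw_dual", "bayes"):
            state = ra.init_state(model, p)
            for r in rewards:
                state = ra.advance(model, p, state, state.y, r, sd=15.0)
                assert 0.0 <= state.k <= 1.0
                assert math.isfinite(state.y)


class TestOneStepPrediction:
    def test_rw_arithmetic(self):
        p = ra.ModelParams(alpha=0.5)
        state = ra.init_state("rw", p)
        mu, _ = ra.one_step_prediction("rw", p, state, 40.0, 60.0)
        assert mu == pytest.approx(50.0)

    def test_zero_error_keeps_observed_prediction(self):
        for model in ("rw", "ph", "aph", "rw_dual", "bayes"):
            p = ra.ModelParams(alpha=0.7, gamma=0.4, nu=0.5)
            state = ra.init_state(model, p)
            mu, _ = ra.one_step_prediction(model, p, state, 42.0, 42.0, sd=10.0)
            assert mu == pytest.approx(42.0)

    def test_ph_matches_hand_unrolled_recursion(self):
        # oracle: manual unroll of k/mu over three observed trials
        p = ra.ModelParams(alpha=0.6, gamma=0.5, C=0.05)
        obs = [(50.0, 70.0), (58.0, 40.0), (49.0, 60.0)]  # (y_obs, reward)
        state = ra.init_state("ph", p)
        mus = []
        for y, r in obs:
            mu, state = ra.one_step_prediction("ph", p, state, y, r)
            mus.append(mu)
        # trial 1: k=0.6, delta=20 -> mu=62; k1=.5*.05*20+.5*.6=0.8
        # trial 2: k=0.8, delta=-18 -> mu=58-14.4=43.6; k2=.5*.05*18+.5*.8=0.85
        # trial 3: k=0.85, delta=11 -> mu=49+9.35=58.35
        assert mus == [pytest.approx(62.0), pytest.approx(43.6),
                       pytest.approx(58.35)]

    def test_missed_trial_advances_on_model_prediction(self):
        p = ra.ModelParams(alpha=0.5)
        state = ra.init_state("rw", p)
        mu, _ = ra.one_step_prediction("rw", p, state, None, 70.0)
        assert mu == pytest.approx(60.0)  # 50 + 0.5 * (70 - 50)


class TestModelParamsValidation:
    @pytest.mark.parametrize("kwargs", [
        {"alpha": 1.5}, {"gamma": -0.1}, {"C": 0.0},
        {"sigma_hat_sq": 0.0}, {"prior_var": -1.0}, {"nu": 2.0},
    ])
    def test_bounds_enforced(self, kwargs):
        with pytest.raises(ValueError):
            ra.ModelParams(**kwargs)

    def test_per_sd_reward_variance(self):
        p = ra.ModelParams(reward_var={5.0: 25.0, 10.0: 100.0})
        assert p.reward_variance(10.0) == 100.0
        with pytest.raises(KeyError):
            p.reward_variance(15.0)
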