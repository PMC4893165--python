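"""Likelihood evaluation, per-subject fitting, comparison and the LRT."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rpeadapt as ra
from rpeadapt.fitting import _prepare, _residuals


def _make_trials(y, r, sd=10.0, subject=0):
    n = len(y)
    return pd.DataFrame({
        "subject": subject, "session": 1, "condition_id": "c1", "sd": sd,
        "ev": 50.0, "trial_in_condition": np.arange(1, n + 1),
        "prediction": y, "reward": r, "rpe": np.array(r) - np.array(y),
        "is_control": False, "payoff": np.array(r) / 10, "missed": False,
    })


class TestNegativeLogLikelihood:
    def test_zero_residual_closed_form(self):
        # all y_m = mu_m with unit variance: NLL = M/2 * log(2*pi)
        p = ra.ModelParams(alpha=1.0, sigma_hat_sq=1.0)
        # alpha=1: mu_{n+1} = r_n; feed y that tracks rewards exactly
        r = [60.0, 40.0, 70.0, 30.0]
        y = [50.0, 60.0, 40.0, 70.0]  # y_1 = y0 = 50
        nll = ra.negative_log_likelihood("rw", p, _make_trials(y, r))
        assert nll == pytest.approx(4 * 0.5 * math.log(2 * math.pi))

    def test_single_trial_closed_form(self):
        # residual 2, variance 4: NLL = 0.5*log(8*pi) + 0.5
        p = ra.ModelParams(alpha=0.5, sigma_hat_sq=4.0)
        nll = ra.negative_log_likelihood("rw", p, _make_trials([52.0], [60.0]))
        assert nll == pytest.approx(0.5 * math.log(8 * math.pi) + 0.5)

    def test_matches_per_trial_density_product(self, aph_subject):
        # oracle: naive per-trial summation of Gaussian log densities along
        # the observed one-step recursion
        trials, _ = aph_subject
        p = ra.ModelParams(alpha=0.4, gamma=0.5, C=0.05, sigma_hat_sq=30.0)
        expected = 0.0
        for _, g in trials.sort_values(
                ["session", "condition_id", "trial_in_condition"]).groupby(
                ["session", "condition_id"], sort=True):
            state = ra.init_state("ph", p)
            for _, row in g.iterrows():
                mu = state.y
                expected -= stats.norm.logpdf(row.prediction, mu,
                                              math.sqrt(30.0))
                _, state = ra.one_step_prediction(
                    "ph", p, state, row.prediction, row.reward, sd=row.sd)
        nll = ra.negative_log_likelihood("ph", p, trials)
        assert nll == pytest.approx(expected, rel=1e-10)

    def test_missed_trials_excluded_but_state_advances(self):
        t = _make_trials([50.0, 60.0, 55.0], [70.0, 40.0, 80.0])
        t.loc[1, "missed"] = True
        t.loc[1, "prediction"] = np.nan
        p = ra.ModelParams(alpha=0.5, sigma_hat_sq=25.0)
        conds = _prepare(t)
        resid = _residuals("rw", {"alpha": 0.5}, conds, 50.0)
        assert len(resid) == 2
        # trial 1: mu=50 resid 0; state: y_use=50 -> mu=60
        # trial 2 missed: y_use=60 -> mu=60+0.5*(40-60)=50
        # trial 3: resid = 55 - 50 = 5
        assert resid == [pytest.approx(0.0), pytest.approx(5.0)]

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            ra.negative_log_likelihood("rw", ra.ModelParams(),
                                       _make_trials([], []))


class TestFitSubject:
    def test_refit_identical_seed_is_identical(self, aph_subject):
        trials, _ = aph_subject
        a = ra.fit_subject("ph", trials, restarts=3,
                           rng=np.random.default_rng(5))
        b = ra.fit_subject("ph", trials, restarts=3,
                           rng=np.random.default_rng(5))
        assert a.loglik == b.loglik
        assert a.params == b.params

    def test_aic_bic_identities(self, aph_subject):
        trials, _ = aph_subject
        f = ra.fit_subject("rw", trials, restarts=3,
                           rng=np.random.default_rng(6))
        assert f.aic == pytest.approx(2 * f.n_free - 2 * f.loglik)
        assert f.bic == pytest.approx(f.n_free * math.log(f.n_obs)
                                      - 2 * f.loglik)
        assert f.n_free == 2  # alpha + sigma_hat_sq

    def test_nll_weakly_decreases_with_more_restarts(self, aph_subject):
        trials, _ = aph_subject
        few = ra.fit_subject("aph", trials, restarts=2,
                             rng=np.random.default_rng(7))
        many = ra.fit_subject("aph", trials, restarts=6,
                              rng=np.random.default_rng(7))
        assert many.loglik >= few.loglik - 1e-9

    def test_rw_alpha_recovered(self, recovery_config):
        rng = np.random.default_rng(8)
        sched = ra.build_schedule(recovery_config, rng)
        params = ra.ModelParams(alpha=0.4, sigma_hat_sq=25.0)
        trials = ra.simulate_agent("rw", params, sched, rng)
        f = ra.fit_subject("rw", trials, restarts=5,
                           rng=np.random.default_rng(9))
        assert abs(f.params.alpha - 0.4) < 0.1

    def test_nested_warm_start_guarantees_ordering(self, aph_subject):
        trials, _ = aph_subject
        fits = ra.fit_subject_models(trials, models=("rw", "ph", "aph"),
                                     restarts=3, rng=np.random.default_rng(10))
        assert fits["ph"].loglik >= fits["rw"].loglik - 1e-6
        assert fits["aph"].loglik >= fits["ph"].loglik - 1e-6


@pytest.fixture(scope="module")
def cohort_fits(recovery_config):
    rng = np.random.default_rng(11)
    trials, _ = ra.simulate_cohort(
        6, "ph", ra.cohort_param_sampler("ph"), recovery_config, rng)
    return ra.fit_cohort(trials, models=("rw", "ph", "aph"), restarts=5,
                         rng=np.random.default_rng(12))


class TestCompareModels:
    def test_antisymmetry_and_winner_totals(self, cohort_fits):
        table = ra.compare_models(cohort_fits)
        for mr in table.models:
            for mc in table.models:
                assert table.d_aic.loc[mr, mc] == pytest.approx(
                    -table.d_aic.loc[mc, mr])
        assert sum(table.aic_winners.values()) == table.n_subjects
        assert sum(table.bic_winners.values()) == table.n_subjects

    def test_ph_cohort_favours_ph_over_rw(self, cohort_fits):
        table = ra.compare_models(cohort_fits)
        assert table.d_aic.loc["ph", "rw"] < 0

    def test_identical_models_give_zero_delta(self, cohort_fits):
        doubled = {s: {"rw": f["ph"], "ph": f["ph"]}  # same fit twice
                   for s, f in cohort_fits.items()}
        table = ra.compare_models(doubled)
        assert table.d_aic.loc["ph", "rw"] == pytest.approx(0.0)

    def test_missing_fits_rejected(self, cohort_fits):
        broken = {s: dict(f) for s, f in cohort_fits.items()}
        first = sorted(broken)[0]
        del broken[first]["aph"]
        with pytest.raises(ValueError, match="missing"):
            ra.compare_models(broken)


class TestFixedEffectsLRT:
    def test_identical_fits_give_null_result(self, aph_subject):
        trials, _ = aph_subject
        ph = ra.fit_subject("ph", trials, restarts=2,
                            rng=np.random.default_rng(13))
        aph = ra.FitResult(**{**ph.__dict__, "model": "aph"})
        res = ra.fixed_effects_lrt({0: ph}, {0: aph}, df_per_subject=1)
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_df_bookkeeping(self, aph_subject):
        trials, _ = aph_subject
        ph = ra.fit_subject("ph", trials, restarts=2,
                            rng=np.random.default_rng(14))
        aph = ra.fit_subject("aph", trials, restarts=2,
                             rng=np.random.default_rng(15))
        fits_r = {s: ph for s in range(27)}
        fits_f = {s: aph for s in range(27)}
        res = ra.fixed_effects_lrt(fits_r, fits_f)
        assert res.df == 27  # one extra free parameter per subject

    def test_non_nested_pair_rejected(self, aph_subject):
        trials, _ = aph_subject
        rw = ra.fit_subject("rw", trials, restarts=2,
                            rng=np.random.default_rng(16))
        bayes = ra.fit_subject("bayes", trials, restarts=2,
                               rng=np.random.default_rng(17))
        with pytest.raises(ValueError, match="nested"):
            ra.fixed_effects_lrt({0: bayes}, {0: rw})


class TestGroupLearningRates:
    def test_per_sd_rates_present_and_bounded(self, aph_subject):
        trials, _ = aph_subject
        fit = ra.fit_group_learning_rates(trials, by="sd", restarts=5,
                                          rng=np.random.default_rng(18))
        assert set(fit.rates) == {5.0, 10.0, 15.0}
        assert all(0.0 <= a <= 1.0 for a in fit.rates.values())
        assert fit.n_free == 6  # 3 alphas + gamma + C + sigma_hat_sq

    def test_mean_early_gain_tracks_rates(self, aph_subject):
        trials, _ = aph_subject
        fit = ra.fit_group_learning_rates(trials, by="sd", restarts=5,
                                          rng=np.random.default_rng(19))
        early = ra.mean_early_gain(trials, fit, by="sd")
        assert set(early) == {5.0, 10.0, 15.0}
        assert all(0.0 <= v <= 1.0 for v in early.values())
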