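"""Fit all candidate learning models to one simulated subject.

Simulates an adaptive Pearce-Hall agent (true nu = 0.8: strong divisive
scaling of prediction errors by log SD), then fits the Bayesian mean tracker,
Rescorla-Wagner, Pearce-Hall and adaptive Pearce-Hall models by
maximum likelihood and prints the information-criterion comparison.  The
generating model should win AIC, and the fitted nu should be near its true
value.
"""

import numpy as np

import rpeadapt as ra


def main() -> None:
    rng = np.random.default_rng(7)
    schedule = ra.build_schedule(ra.TaskConfig(), rng)
    true = ra.ModelParams(alpha=0.5, gamma=0.5, C=0.05, nu=0.8,
                          sigma_hat_sq=25.0)
    trials = ra.simulate_agent("aph", true, schedule, rng)

    fits = ra.fit_subject_models(trials, models=("bayes", "rw", "ph", "aph"),
                                 restarts=10, rng=np.random.default_rng(1))

    print(f"{'model':8} {'loglik':>9} {'AIC':>8} {'BIC':>8}  free parameters")
    for model, fit in fits.items():
        free = {n: round(ra.fitting._get_param(fit.params, n), 3)
                for n in fit.free_names}
        print(f"{model:8} {fit.loglik:9.2f} {fit.aic:8.1f} {fit.bic:8.1f}  "
              f"{free}")
    print(f"\ntrue nu = {true.nu}, fitted nu = {fits['aph'].params.nu:.3f}")
    print("Lower AIC/BIC is better; the adaptive PH row should win because "
          "the agent really compressed its updates in high-SD conditions.\n"
          "A single subject identifies nu only noisily - cohort-level rank "
          "correlation between true and fitted nu is the reliable recovery "
          "measure (see the test suite).")


if __name__ == "__main__":
    main()
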