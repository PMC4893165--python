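"""Adaptive coding in simulated per-trial response amplitudes.

Simulates scalar outcome responses whose prediction-error coding slope adapts
to the condition SD with strength psi, then (1) recovers the per-SD slopes,
(2) computes the neural adaptation index Psi (R^2 of slopes on 1/SD), and
(3) asks whether a normalised code (RPE/SD) or a raw RPE code better explains
the responses when both regressors compete jointly.
"""

import numpy as np

import rpeadapt as ra


def main() -> None:
    rng = np.random.default_rng(21)
    trials, _ = ra.simulate_cohort(6, "aph", ra.cohort_param_sampler("aph"),
                                   ra.TaskConfig(), rng)
    subjects = sorted(trials.subject.unique())

    for psi in (0.0, 0.5, 1.0):
        resp = ra.simulate_cohort_responses(
            trials, {s: psi for s in subjects}, np.random.default_rng(22))
        slopes = ra.estimate_slopes(resp, by=("sd",)).set_index("sd")["slope"]
        index = ra.neural_adaptation_index(dict(slopes)).r_squared
        nvr = ra.normalized_vs_raw(resp)
        print(f"psi = {psi:3.1f}: slopes "
              f"SD5 {slopes[5.0]:5.2f}, SD10 {slopes[10.0]:5.2f}, "
              f"SD15 {slopes[15.0]:5.2f} | Psi = {index:.3f} | "
              f"raw coef {nvr.mean_raw:6.2f} vs normalised {nvr.mean_norm:6.2f}")

    print("\npsi = 0 gives equal slopes (absolute coding) and the raw-RPE "
          "regressor wins; psi = 1 gives slopes proportional to 1/SD and the "
          "normalised regressor wins.  Note that Psi, a three-point R^2, is "
          "only meaningful alongside the slope differences themselves: with "
          "near-equal slopes it fits residual noise.")


if __name__ == "__main__":
    main()
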