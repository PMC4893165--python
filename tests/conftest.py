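import numpy as np
import pytest

import rpeadapt as ra


@pytest.fixture(scope="session")
def canonical_config():
    return ra.TaskConfig()


@pytest.fixture(scope="session")
def recovery_config():
    """126-trial schedule (6 x 21) without control trials, for recovery runs."""
    return ra.TaskConfig(trials_per_condition=21, control_fraction=0.0)


@pytest.fixture(scope="session")
def aph_subject(canonical_config):
    """One adaptive-PH agent on the canonical task (150 trials)."""
    rng = np.random.default_rng(424242)
    schedule = ra.build_schedule(canonical_config, rng)
    params = ra.ModelParams(alpha=0.5, gamma=0.5, C=0.05, nu=0.8,
                            sigma_hat_sq=25.0)
    trials = ra.simulate_agent("aph", params, schedule, rng)
    return trials, params


@pytest.fixture(scope="session")
def small_cohort(canonical_config):
    """Five adaptive-PH agents with heterogeneous nu, canonical task."""
    rng = np.random.default_rng(97531)
    return ra.simulate_cohort(5, "aph", ra.cohort_param_sampler("aph"),
                              canonical_config, rng)
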