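import numpy as np
import pandas as pd
import pytest

from ergogwas import SimConfig, simulate_cohort, simulate_traces


@pytest.fixture(scope="session")
def small_cohort():
    """100 participants with default (noisy) study conditions."""
    cohort, truth = simulate_cohort(100, 11)
    return cohort, truth


@pytest.fixture(scope="session")
def noiseless_config():
    return SimConfig(hr_noise_sd=0.0, spike_prob=0.0, cadence_outlier_prob=0.0)


@pytest.fixture(scope="session")
def noiseless_traces(small_cohort, noiseless_config):
    cohort, truth = small_cohort
    return simulate_traces(cohort, truth, 12, noiseless_config)


def make_ramp_session(pid="P1", risk="minimal", n_const=30, n_ramp=60,
                      hr_rest=70.0, hr_per_watt=0.4, w0=40.0, w1=130.0,
                      age=50.0, weight=75.0, cadence=60.0, hr_noise=None):
    """Hand-constructed exercise-phase-only session with exact linear HR."""
    from ergogwas.ergo import ErgoSession

    wl = np.concatenate([np.full(n_const, w0),
                         np.linspace(w0, w1, n_ramp + 1)[1:]])
    hr = hr_rest + hr_per_watt * wl
    if hr_noise is not None:
        hr = hr + hr_noise
    obs = pd.DataFrame({
        "phase": "exercise",
        "trend": np.arange(1, n_const + n_ramp + 1),
        "heart_rate": hr, "workload": wl,
        "cadence": np.full(n_const + n_ramp, cadence),
    })
    return ErgoSession(participant_id=pid, risk_category=risk, age=age,
                       weight=weight, observations=obs)
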