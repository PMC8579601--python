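"""CRF derivation: window selection, QC boundaries, filtering, the two
phenotype fits and their oracles, and parameter recovery on synthetic data."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_ramp_session
from ergogwas import (SimConfig, age_predicted_max_hr, derive_crf_phenotypes,
                      derive_slope, derive_vo2max, lowpass_filter,
                      simulate_traces)
from ergogwas.ergo import (SessionExcluded, apply_qc_filters,
                           select_exercise_window, sessions_from_traces)


# ------------------------------------------------------------ window selection
def test_ramp_window_drops_constant_leadin():
    s = make_ramp_session(n_const=30, n_ramp=60)
    win = select_exercise_window(s)
    assert len(win) == 60
    assert (np.diff(win["workload"]) > 0).all()


def test_medium_risk_uses_full_exercise_phase():
    s = make_ramp_session(risk="medium", n_const=90, n_ramp=0)
    assert len(select_exercise_window(s)) == 90


@pytest.mark.parametrize("risk,method,flag", [
    ("high", "Bicycle", "bad_risk"),
    ("minimal", "Treadmill", "bad_method"),
])
def test_ineligible_sessions_are_excluded_with_reason(risk, method, flag):
    s = make_ramp_session(risk=risk)
    s.method = method
    with pytest.raises(SessionExcluded) as err:
        select_exercise_window(s)
    assert err.value.flag == flag


# ----------------------------------------------------------------- cadence QC
def test_cadence_bounds_are_inclusive():
    s = make_ramp_session(n_const=0, n_ramp=24)
    obs = s.observations.copy()
    obs.loc[obs.index[:4], "cadence"] = [34.0, 35.0, 125.0, 126.0]
    kept = apply_qc_filters(obs, min_observations=1)
    assert len(kept) == 22
    assert 34.0 not in kept["cadence"].values
    assert 126.0 not in kept["cadence"].values
    assert {35.0, 125.0} <= set(kept["cadence"])


@pytest.mark.parametrize("n,ok", [(19, False), (20, True)])
def test_minimum_observation_rule(n, ok):
    s = make_ramp_session(n_const=0, n_ramp=n)
    if ok:
        assert len(apply_qc_filters(s.observations)) == n
    else:
        with pytest.raises(SessionExcluded) as err:
            apply_qc_filters(s.observations)
        assert err.value.flag == "low_cadence_n"


# -------------------------------------------------------------------- filter
def test_filter_preserves_dc():
    out = lowpass_filter(np.full(50, 100.0))
    np.testing.assert_allclose(out, 100.0, atol=1e-9)


def test_filter_attenuates_nyquist_component():
    n = 256
    sign = (-1.0) ** np.arange(n)
    x = 100.0 + 10.0 * sign
    out = lowpass_filter(x, order=4, cutoff_fraction=0.1)
    # |H| at Nyquist is (1 + (1/0.1)^8)^-1/2 ~ 1e-4, applied twice by the
    # forward-backward pass; measure the Nyquist Fourier amplitude
    amp_in = abs(np.mean(x * sign))
    amp_out = abs(np.mean(out * sign))
    assert amp_out < 0.01 * amp_in
    # and the interior of the signal is flat once edge transients decay
    assert np.abs(out[n // 4: -n // 4] - 100.0).max() < 0.01 * 10.0


def test_filter_denoises_a_linear_trend():
    rng = np.random.default_rng(42)
    truth = 70 + 0.5 * np.arange(90.0)
    noisy = truth + rng.normal(0, 3, 90)
    filt = lowpass_filter(noisy)
    assert np.sqrt(np.mean((filt - truth) ** 2)) \
        < np.sqrt(np.mean((noisy - truth) ** 2))


def test_filter_idempotent_on_band_limited_signal():
    # full periods with odd symmetry at both ends, frequency well below the
    # cutoff, so the reflective extension is exact and |H| ~ 1
    t = np.arange(201.0)
    x = 100 + 5 * np.sin(2 * np.pi * 0.005 * t)
    once = lowpass_filter(x)
    twice = lowpass_filter(once)
    assert np.sqrt(np.mean((twice - once) ** 2)) < 1e-6 * np.std(once)


def test_too_short_sequence_passes_through_unfiltered():
    x = np.arange(5.0)
    np.testing.assert_array_equal(lowpass_filter(x), x)


# ------------------------------------------------------------------ formulas
@pytest.mark.parametrize("age,expected", [(40, 180.0), (69, 159.7)])
def test_age_predicted_max_hr(age, expected):
    assert age_predicted_max_hr(age) == pytest.approx(expected)


def test_age_predicted_max_hr_rejects_nonpositive_age():
    with pytest.raises(ValueError):
        age_predicted_max_hr(0)


def test_vo2max_endpoints_two_point_example():
    # line through (90 bpm, 40 W) and (150 bpm, 100 W) evaluated at
    # HRmax(40y) = 180 bpm: slope 1 W/bpm -> 130 W; /80 kg = 1.625 W/kg
    obs = pd.DataFrame({"heart_rate": [90.0, 150.0], "workload": [40.0, 100.0]})
    vo2, wlmax, h0, h1, flags = derive_vo2max(obs, age=40, weight=80,
                                              mode="endpoints")
    assert wlmax == pytest.approx(130.0)
    assert vo2 == pytest.approx(1.625)
    assert (h0, h1) == (90.0, 150.0)
    assert not flags


def test_vo2max_constant_workload_flags_degenerate():
    obs = pd.DataFrame({"heart_rate": np.linspace(90, 120, 30),
                        "workload": np.full(30, 40.0)})
    vo2, wlmax, *_, flags = derive_vo2max(obs, age=40, weight=80)
    assert wlmax == 40.0 and vo2 == pytest.approx(0.5)
    assert "degenerate_workload" in flags


def test_vo2max_inversely_proportional_to_weight():
    obs = pd.DataFrame({"heart_rate": np.linspace(90, 150, 40),
                        "workload": np.linspace(40, 100, 40)})
    v1, *_ = derive_vo2max(obs, age=50, weight=70)
    v2, *_ = derive_vo2max(obs, age=50, weight=140)
    assert v1 == pytest.approx(2 * v2)


def test_vo2max_scale_equivariant_in_workload():
    rng = np.random.default_rng(0)
    obs = pd.DataFrame({"heart_rate": np.linspace(90, 150, 40)
                        + rng.normal(0, 2, 40),
                        "workload": np.linspace(40, 100, 40)})
    v1, *_ = derive_vo2max(obs, age=50, weight=70)
    obs2 = obs.assign(workload=obs["workload"] * 3.0)
    v2, *_ = derive_vo2max(obs2, age=50, weight=70)
    assert v2 == pytest.approx(3 * v1)


def test_vo2max_endpoints_equal_hr_is_excluded():
    obs = pd.DataFrame({"heart_rate": [100.0, 100.0], "workload": [40.0, 80.0]})
    with pytest.raises(SessionExcluded):
        derive_vo2max(obs, age=40, weight=80, mode="endpoints")


# --------------------------------------------------------------------- slope
def test_slope_exact_on_linear_input():
    obs = pd.DataFrame({"trend": np.arange(1, 31),
                        "heart_rate": 70 + 0.8 * np.arange(1, 31)})
    b0, b1, flags = derive_slope(obs)
    assert b1 == pytest.approx(0.8)
    assert b0 == pytest.approx(70.0)
    assert not flags


def test_zero_slope_retained_negative_excluded():
    obs = pd.DataFrame({"trend": np.arange(1, 25),
                        "heart_rate": np.full(24, 90.0)})
    _, b1, flags = derive_slope(obs)
    assert b1 == 0.0 and "negative_slope" not in flags
    obs2 = obs.assign(heart_rate=100 - 0.3 * obs["trend"])
    _, b1, flags = derive_slope(obs2)
    assert b1 < 0 and "negative_slope" in flags


def test_slope_matches_normal_equation_oracle():
    rng = np.random.default_rng(7)
    trend = np.arange(1.0, 41.0)
    hr = 75 + 0.6 * trend + rng.normal(0, 3, 40)
    obs = pd.DataFrame({"trend": trend, "heart_rate": hr})
    b0, b1, _ = derive_slope(obs)
    X = np.column_stack([np.ones(40), trend])
    oracle = np.linalg.inv(X.T @ X) @ X.T @ hr      # explicit (X'X)^-1 X'y
    assert b0 == pytest.approx(oracle[0], abs=1e-10)
    assert b1 == pytest.approx(oracle[1], abs=1e-10)


def test_hr_shift_moves_intercept_not_slope():
    rng = np.random.default_rng(8)
    obs = pd.DataFrame({"trend": np.arange(1.0, 41.0),
                        "heart_rate": 75 + 0.6 * np.arange(1.0, 41.0)
                        + rng.normal(0, 2, 40)})
    b0a, b1a, _ = derive_slope(obs)
    b0b, b1b, _ = derive_slope(obs.assign(heart_rate=obs["heart_rate"] + 10))
    assert b1b == pytest.approx(b1a, abs=1e-10)
    assert b0b == pytest.approx(b0a + 10, abs=1e-8)


# ------------------------------------------------------------- orchestration
def test_noiseless_cohort_recovers_analytic_truth(small_cohort,
                                                  noiseless_traces):
    cohort, truth = small_cohort
    crf, _ = derive_crf_phenotypes(sessions_from_traces(noiseless_traces,
                                                        cohort))
    m = crf.merge(truth, on="participant_id").merge(
        cohort[["participant_id", "risk_category"]], on="participant_id")
    ramped = m[m["risk_category"].isin(["minimal", "small"])]
    assert len(ramped) > 50
    np.testing.assert_allclose(ramped["crf_vo2max"], ramped["true_vo2max"],
                               atol=1e-6)


def test_exclusion_counts_partition_the_input(small_cohort):
    cohort, truth = small_cohort
    traces = simulate_traces(cohort, truth, 13, SimConfig())
    crf, excl = derive_crf_phenotypes(sessions_from_traces(traces, cohort))
    n_excl = int(excl["n"].sum()) if len(excl) else 0
    assert len(crf) + n_excl == cohort["participant_id"].nunique()
    n_high = int((cohort["risk_category"] == "high").sum())
    assert int(excl.set_index("reason").loc["bad_risk", "n"]) == n_high


def test_slope_estimate_unbiased_under_ar1_noise():
    # 300 replicates of a known ramp with AR(1) noise (sd 3): the mean
    # estimated slope should sit within Monte-Carlo error of the truth
    rho, sd = 0.6, 3.0
    trend = np.arange(1.0, 61.0)
    true_slope = 0.5
    est = []
    rng = np.random.default_rng(99)
    for _ in range(300):
        innov = rng.normal(0, sd * np.sqrt(1 - rho ** 2), 60)
        noise = np.empty(60)
        noise[0] = rng.normal(0, sd)
        for t in range(1, 60):
            noise[t] = rho * noise[t - 1] + innov[t]
        obs = pd.DataFrame({"trend": trend,
                            "heart_rate": 70 + true_slope * trend + noise})
        est.append(derive_slope(obs,
                                filtered_hr=lowpass_filter(
                                    obs["heart_rate"].to_numpy()))[1])
    est = np.asarray(est)
    mc_se = est.std(ddof=1) / np.sqrt(len(est))
    assert abs(est.mean() - true_slope) < 4 * mc_se
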