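"""Generator behaviour: determinism, configured distributions, planted
structure (LD, spikes, ramp shape) and trace round-tripping."""

import numpy as np
import pandas as pd
import pytest

from ergogwas import (GenotypeMatrix, SimConfig, ld_r2, simulate_cohort,
                      simulate_ergo_session, simulate_genotypes,
                      simulate_phenotypes_and_outcomes, simulate_traces)
from ergogwas.io import read_traces, write_traces


def test_cohort_seeded_determinism():
    a_cohort, a_truth = simulate_cohort(10, seed=1)
    b_cohort, b_truth = simulate_cohort(10, seed=1)
    pd.testing.assert_frame_equal(a_cohort, b_cohort)
    pd.testing.assert_frame_equal(a_truth, b_truth)
    c_cohort, _ = simulate_cohort(10, seed=2)
    assert not a_cohort.equals(c_cohort)


def test_cohort_age_distribution_matches_config():
    cohort, _ = simulate_cohort(1000, seed=7)
    # age ~ Uniform(40, 69): mean 54.5, SE = (69-40)/sqrt(12)/sqrt(n)
    se = (69 - 40) / np.sqrt(12) / np.sqrt(1000)
    assert abs(cohort["age"].mean() - 54.5) < 3 * se
    assert cohort["age"].between(40, 69).all()
    assert (cohort["weight"] > 0).all()
    assert cohort["participant_id"].is_unique


def test_cohort_rejects_nonpositive_n():
    with pytest.raises(ValueError):
        simulate_cohort(0, seed=1)


def test_true_vo2max_is_analytic_in_truth_components():
    cohort, truth = simulate_cohort(200, seed=3)
    expected = ((208 - 0.7 * cohort["age"].to_numpy())
                - truth["hr_rest"].to_numpy()) \
        / truth["hr_per_watt"].to_numpy() / cohort["weight"].to_numpy()
    np.testing.assert_allclose(truth["true_vo2max"], expected, rtol=1e-12)
    assert (truth["true_vo2max"] > 0).all()


def test_noiseless_session_hr_exactly_linear_in_workload():
    cohort, truth = simulate_cohort(5, seed=4)
    cfg = SimConfig(hr_noise_sd=0.0, spike_prob=0.0)
    row = cohort.iloc[0].copy()
    row["risk_category"] = "minimal"
    trow = truth.iloc[0]
    obs = simulate_ergo_session(row, trow, 1, cfg)
    ex = obs[obs["phase"] == "exercise"]
    pred = trow["hr_rest"] + trow["hr_per_watt"] * ex["workload"]
    np.testing.assert_allclose(ex["heart_rate"], pred, rtol=1e-12)
    # exercise phase long enough for the 20-observation QC rule
    assert len(ex) >= 20


def test_session_phase_structure_and_ramp_shape():
    cohort, truth = simulate_cohort(3, seed=5)
    row = cohort.iloc[0].copy()
    trow = truth.iloc[0]
    for risk in ("minimal", "small"):
        row["risk_category"] = risk
        ex = simulate_ergo_session(row, trow, 2)
        ex = ex[ex["phase"] == "exercise"]
        wl = ex["workload"].to_numpy()
        n_const = int((wl == wl[0]).sum())
        # 2-min lead-in (30 samples at 4 s) plus the ramp-start boundary point
        assert abs(n_const - 120 / 4) <= 1
        assert np.all(np.diff(wl[n_const - 1:]) > 0)    # strict 4-min ramp
    row["risk_category"] = "medium"
    ex = simulate_ergo_session(row, trow, 2)
    ex = ex[ex["phase"] == "exercise"]
    assert ex["workload"].nunique() == 1
    with pytest.raises(ValueError):
        row2 = row.copy()
        row2["risk_category"] = "extreme"
        simulate_ergo_session(row2, trow, 2)


def test_spike_fraction_matches_configured_probability():
    cohort, truth = simulate_cohort(1, seed=6)
    cfg = SimConfig(hr_noise_sd=0.0, spike_prob=0.05, spike_amplitude=30.0)
    row = cohort.iloc[0].copy()
    row["risk_category"] = "medium"   # flat trend isolates the spikes
    trow = truth.iloc[0]
    n_tot, n_spike = 0, 0
    for s in range(40):
        obs = simulate_ergo_session(row, trow, s, cfg)
        ex = obs[obs["phase"] == "exercise"]
        base = trow["hr_rest"] + trow["hr_per_watt"] * ex["workload"]
        dev = np.abs(ex["heart_rate"] - base)
        n_spike += int((dev > 9).sum())   # 3x a nominal 3-bpm noise scale
        n_tot += len(ex)
    frac = n_spike / n_tot
    se = np.sqrt(0.05 * 0.95 / n_tot)
    assert abs(frac - 0.05) < 4 * se


def test_genotypes_perfect_copying_gives_r2_one():
    g = simulate_genotypes(300, 10, 1, (0.2, 0.4), seed=1, copy_prob=1.0)
    for j in range(1, 10):
        assert ld_r2(g, 0, j) == pytest.approx(1.0)


def test_genotypes_no_copying_gives_near_zero_r2():
    g = simulate_genotypes(2000, 20, 1, (0.2, 0.4), seed=2, copy_prob=0.0)
    r2s = [ld_r2(g, i, j) for i in range(20) for j in range(i + 1, 20)]
    # under independence E[r2] ~ 1/(n-1)
    assert np.mean(r2s) < 5.0 / 1999


def test_genotype_allele_frequency_recovers_maf_spec():
    g = simulate_genotypes(500, 1, 1, (0.05, 0.5), seed=3, maf=0.3)
    se = np.sqrt(0.3 * 0.7 / (2 * 500))
    assert abs(g.allele_freq()[0] - 0.3) < 3 * se
    assert g.dosages.min() >= 0 and g.dosages.max() <= 2


def test_genotype_positions_strictly_increasing_per_chromosome():
    g = simulate_genotypes(100, 60, 12, (0.05, 0.5), seed=4)
    for _, sub in g.variants.groupby("chrom"):
        assert (np.diff(sub["pos"]) > 0).all()
    with pytest.raises(ValueError):
        simulate_genotypes(10, 5, 6, (0.05, 0.5), seed=1)
    with pytest.raises(ValueError):
        simulate_genotypes(10, 5, 2, (0.5, 0.1), seed=1)


def test_phenotypes_outcomes_structure_and_missing_causal_error():
    cohort, truth = simulate_cohort(300, seed=8)
    g = simulate_genotypes(300, 30, 6, (0.1, 0.5), seed=8,
                           sample_ids=list(cohort["participant_id"]))
    phen, dx, eff = simulate_phenotypes_and_outcomes(cohort, g, truth, 9)
    assert set(["pheno", "pa_accel_mg", "good_wear_time"]) <= set(phen.columns)
    assert (phen["pa_accel_mg"] > 0).all()
    assert set(dx.columns) == {"participant_id", "icd10_code"}
    bad = pd.DataFrame({"variant_id": ["rs_not_there"],
                        "beta_male": [0.2], "beta_female": [0.2]})
    with pytest.raises(KeyError):
        simulate_phenotypes_and_outcomes(cohort, g, truth, 9,
                                         variant_effects=bad)


def test_trace_table_roundtrips_through_tsv(tmp_path, small_cohort,
                                            noiseless_traces):
    path = tmp_path / "traces.tsv"
    write_traces(noiseless_traces, path, stage="simulate", config_hash="abc")
    back = read_traces(path)
    pd.testing.assert_frame_equal(back, noiseless_traces, check_exact=False,
                                  rtol=1e-12)


def test_vcf_and_dosage_tsv_roundtrip(tmp_path):
    g = simulate_genotypes(40, 12, 3, (0.1, 0.5), seed=10)
    g.to_vcf(tmp_path / "g.vcf")
    g2 = GenotypeMatrix.from_vcf(tmp_path / "g.vcf")
    np.testing.assert_allclose(g.dosages, g2.dosages)
    assert list(g.variants["variant_id"]) == list(g2.variants["variant_id"])
    assert g2.samples == g.samples
    g.to_dosage_tsv(tmp_path / "g.tsv")
    g3 = GenotypeMatrix.from_dosage_tsv(tmp_path / "g.tsv")
    np.testing.assert_allclose(g.dosages, g3.dosages, atol=1e-6)
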