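"""Synthetic biobank-style cohort generator with known ground truth.

Emulates the five inputs the analysis pipeline consumes — submaximal
cycle-ramp-test traces, a cohort covariate table, accelerometer summaries
with QC flags, genotype dosages with block LD structure, and long-format
ICD-10 diagnosis records — so that every downstream stage (CRF derivation,
PA QC, residualization, association, clumping, heterogeneity meta-analysis,
disease deciles) can be tested for parameter recovery without any external
data.

Ground truth: each participant's heart-rate response is linear in workload
(resting rate ``hr_rest`` plus ``hr_per_watt`` bpm per watt), so the
analytically true fitness value is::

    true_vo2max = ((208 - 0.7 * age) - hr_rest) / hr_per_watt / weight

in W/kg — the workload at the age-predicted maximum heart rate divided by
body weight.  Genetic effects (optionally sex-specific) are planted on a
quantitative trait; disease liability follows a logistic dose-response in a
standardized phenotype.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig
from .genotypes import GenotypeMatrix

__all__ = [
    "simulate_cohort",
    "simulate_ergo_session",
    "simulate_traces",
    "simulate_genotypes",
    "default_variant_effects",
    "simulate_phenotypes_and_outcomes",
]

RISK_CATEGORIES = ("minimal", "small", "medium", "high")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _categorical(rng, probs: dict, n: int) -> np.ndarray:
    levels = list(probs)
    return rng.choice(levels, size=n, p=[probs[k] for k in levels])


# --------------------------------------------------------------------- cohort
def simulate_cohort(n: int, seed, config: SimConfig | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw ``n`` participants and their cardiorespiratory ground truth.

    Returns ``(cohort, truth)``: the covariate table (id, sex, age, weight,
    SES, centre, array, 10 PCs, risk category, smoking, drinking) and the
    per-participant truth table (hr_rest, hr_per_watt, true_vo2max).
    Deterministic given ``(n, seed, config)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or SimConfig()
    config.validate()
    rng = _rng(seed)

    pid = np.array([f"S{i:06d}" for i in range(1, n + 1)])
    sex = np.where(rng.random(n) < config.p_male, "male", "female")
    age = rng.uniform(config.age_min, config.age_max, size=n)
    wmean = np.where(sex == "male", config.weight_mean_male, config.weight_mean_female)
    weight = np.maximum(rng.normal(wmean, config.weight_sd), config.weight_min)
    ses = rng.normal(0.0, config.ses_sd, size=n)
    centre = rng.integers(1, config.n_centres + 1, size=n)
    array = np.where(rng.random(n) < config.p_array_a, "A", "B")
    risk = _categorical(rng, config.risk_frequencies, n)
    smoking = _categorical(rng, config.smoking_probs, n)
    drinking = _categorical(rng, config.drinking_probs, n)
    pcs = rng.normal(0.0, 1.0, size=(n, 10))

    cohort = pd.DataFrame({
        "participant_id": pid, "sex": sex, "age": age, "weight": weight,
        "ses": ses, "centre": [f"centre_{c}" for c in centre], "array": array,
        "risk_category": risk, "smoking": smoking, "drinking": drinking,
    })
    for k in range(10):
        cohort[f"pc{k + 1}"] = pcs[:, k]

    hr_rest = np.clip(rng.normal(config.hr_rest_mean, config.hr_rest_sd, size=n),
                      config.hr_rest_min, config.hr_rest_max)
    sigma = np.sqrt(np.log1p(config.hr_per_watt_cv ** 2))
    hr_per_watt = config.hr_per_watt_mean * np.exp(
        rng.normal(0.0, sigma, size=n) - sigma ** 2 / 2.0)
    hr_age_max = 208.0 - 0.7 * age
    true_vo2max = (hr_age_max - hr_rest) / hr_per_watt / weight
    if not (np.all(np.isfinite(true_vo2max)) and np.all(true_vo2max > 0)):
        raise RuntimeError("generated true_vo2max not finite and positive")

    truth = pd.DataFrame({
        "participant_id": pid, "hr_rest": hr_rest, "hr_per_watt": hr_per_watt,
        "true_vo2max": true_vo2max,
    })
    return cohort, truth


# ---------------------------------------------------------------- ramp traces
def _phase_times(duration: float, dt: float) -> np.ndarray:
    return np.arange(0.0, duration - 1e-9, dt)


def simulate_ergo_session(row, truth_row, seed, config: SimConfig | None = None
                          ) -> pd.DataFrame:
    """Simulate one participant's cycle-ramp-test trace.

    Protocol: ~15 s pre-test, 6 min exercise, 1 min recovery, sampled every
    ``sampling_interval_s`` seconds.  For minimal/small risk the exercise
    phase is a 2-min constant lead-in followed by a 4-min linear workload
    ramp; medium risk cycles at constant workload throughout.  Heart rate is
    ``hr_rest + hr_per_watt * workload`` plus stationary AR(1) noise and
    occasional spike artefacts; cadence is normal around 60 RPM with rare
    out-of-range excursions.
    """
    config = config or SimConfig()
    rng = _rng(seed)
    risk = row["risk_category"]
    if risk not in RISK_CATEGORIES:
        raise ValueError(f"unknown risk category {risk!r}")

    dt = config.sampling_interval_s
    t_pre = _phase_times(config.pretest_duration_s, dt)
    t_ex = _phase_times(config.exercise_duration_s, dt)
    t_rec = _phase_times(config.recovery_duration_s, dt)

    w0 = config.workload_start.get(risk, config.workload_start["medium"])
    if risk in ("minimal", "small"):
        ramp_h = config.workload_ramp_height[risk]
        t_const = config.constant_duration_s
        t_ramp = config.exercise_duration_s - t_const
        wl_ex = np.where(t_ex < t_const, w0,
                         w0 + ramp_h * (t_ex - t_const) / t_ramp)
    else:  # medium (and high, which downstream excludes)
        wl_ex = np.full_like(t_ex, w0)

    hr_rest = truth_row["hr_rest"]
    hpw = truth_row["hr_per_watt"]
    hr_pre = np.full_like(t_pre, hr_rest + hpw * 0.0)
    hr_ex = hr_rest + hpw * wl_ex
    hr_rec = hr_rest + (hr_ex[-1] - hr_rest) * np.exp(-t_rec / 30.0)

    hr = np.concatenate([hr_pre, hr_ex, hr_rec])
    n_tot = hr.size

    if config.hr_noise_sd > 0:
        rho = config.hr_noise_rho
        innov = rng.normal(0.0, config.hr_noise_sd * np.sqrt(1 - rho ** 2), n_tot)
        noise = np.empty(n_tot)
        noise[0] = rng.normal(0.0, config.hr_noise_sd)
        for t in range(1, n_tot):
            noise[t] = rho * noise[t - 1] + innov[t]
        hr = hr + noise
    if config.spike_prob > 0:
        spikes = rng.random(n_tot) < config.spike_prob
        signs = rng.choice([-1.0, 1.0], size=n_tot)
        hr = hr + spikes * signs * config.spike_amplitude

    cadence = rng.normal(config.cadence_mean, config.cadence_sd, n_tot)
    if config.cadence_outlier_prob > 0:
        out = rng.random(n_tot) < config.cadence_outlier_prob
        low = rng.random(n_tot) < 0.5
        cadence = np.where(out & low, rng.uniform(0.0, 34.0, n_tot), cadence)
        cadence = np.where(out & ~low, rng.uniform(126.0, 160.0, n_tot), cadence)

    phases = (["pretest"] * t_pre.size + ["exercise"] * t_ex.size
              + ["recovery"] * t_rec.size)
    trend = np.concatenate([np.arange(1, t_pre.size + 1),
                            np.arange(1, t_ex.size + 1),
                            np.arange(1, t_rec.size + 1)])
    workload = np.concatenate([np.zeros(t_pre.size), wl_ex, np.zeros(t_rec.size)])

    return pd.DataFrame({
        "participant_id": row["participant_id"], "phase": phases, "trend": trend,
        "heart_rate": hr, "workload": workload, "cadence": cadence,
    })


def simulate_traces(cohort: pd.DataFrame, truth: pd.DataFrame, seed,
                    config: SimConfig | None = None) -> pd.DataFrame:
    """Simulate traces for a whole cohort (long format, one row per
    observation).  Each participant gets an independent child stream of the
    root seed, so the table is deterministic and order-independent."""
    config = config or SimConfig()
    truth_idx = truth.set_index("participant_id")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(len(cohort))
    parts = []
    for child, (_, row) in zip(children, cohort.iterrows()):
        trow = truth_idx.loc[row["participant_id"]]
        parts.append(simulate_ergo_session(row, trow, np.random.default_rng(child),
                                           config))
    return pd.concat(parts, ignore_index=True)


# ------------------------------------------------------------------ genotypes
def simulate_genotypes(n_samples: int, n_variants: int, n_blocks: int,
                       maf_range=(0.05, 0.5), seed=0, copy_prob: float = 0.9,
                       sample_ids: list[str] | None = None,
                       maf: float | np.ndarray | None = None,
                       config: SimConfig | None = None) -> GenotypeMatrix:
    """Simulate dosages in LD blocks via haplotype copying.

    Within a block every variant shares one MAF (drawn from ``maf_range``
    unless ``maf`` is given); each haplotype copies the previous variant's
    allele with probability ``copy_prob`` and otherwise draws a fresh
    Bernoulli(MAF) allele, giving adjacent-variant allele correlation equal
    to ``copy_prob`` and geometric LD decay within a block.  Blocks are
    independent, laid out on chromosomes with strictly increasing 1-based
    positions and a large inter-block gap.
    """
    if n_blocks > n_variants:
        raise ValueError("n_blocks must be <= n_variants")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("degenerate maf_range")
    config = config or SimConfig()
    rng = _rng(seed)
    if sample_ids is None:
        sample_ids = [f"S{i:06d}" for i in range(1, n_samples + 1)]

    block_bounds = np.array_split(np.arange(n_variants), n_blocks)
    if maf is None:
        block_maf = rng.uniform(lo, hi, size=n_blocks)
        maf_vec = np.concatenate([np.full(len(b), m)
                                  for b, m in zip(block_bounds, block_maf)])
    else:
        maf_vec = np.broadcast_to(np.asarray(maf, dtype=float), (n_variants,)).copy()

    haps = np.empty((n_variants, 2 * n_samples), dtype=np.int8)
    alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    chroms, positions = [], []
    cursor = {}
    for b, idx in enumerate(block_bounds):
        chrom = str(b % config.n_chromosomes + 1)
        pos = cursor.get(chrom, 0) + config.between_block_gap_bp
        for k, j in enumerate(idx):
            fresh = (rng.random(2 * n_samples) < maf_vec[j]).astype(np.int8)
            if k == 0:
                haps[j] = fresh
            else:
                copy = rng.random(2 * n_samples) < copy_prob
                haps[j] = np.where(copy, haps[idx[k - 1]], fresh)
            chroms.append(chrom)
            positions.append(pos)
            pos += config.within_block_spacing_bp
        cursor[chrom] = pos

    dosages = (haps[:, :n_samples] + haps[:, n_samples:]).astype(float)
    a0a1 = [alleles[i % len(alleles)] for i in range(n_variants)]
    variants = pd.DataFrame({
        "chrom": chroms, "pos": positions,
        "variant_id": [f"rs{c}_{p}" for c, p in zip(chroms, positions)],
        "a1": [a[1] for a in a0a1], "a0": [a[0] for a in a0a1],
    })
    return GenotypeMatrix(dosages, variants, sample_ids)


# ------------------------------------------------- phenotypes, PA and disease
def default_variant_effects(genotypes: GenotypeMatrix,
                            config: SimConfig | None = None) -> pd.DataFrame:
    """Default causal architecture: one shared-effect variant, one male-only
    and one female-only variant, evenly spaced across the panel.  Betas are
    in SD units of the quantitative trait."""
    config = config or SimConfig()
    m = genotypes.n_variants
    picks = sorted({m // 6, m // 2, (5 * m) // 6})
    ids = [genotypes.variants["variant_id"].iloc[i] for i in picks]
    rows = [
        (ids[0], config.causal_beta_shared, config.causal_beta_shared),
        (ids[min(1, len(ids) - 1)], config.causal_beta_male_only, 0.0),
        (ids[min(2, len(ids) - 1)], 0.0, config.causal_beta_female_only),
    ]
    return pd.DataFrame(rows, columns=["variant_id", "beta_male", "beta_female"]
                        ).drop_duplicates("variant_id")


def simulate_phenotypes_and_outcomes(
        cohort: pd.DataFrame, genotypes: GenotypeMatrix | None,
        truth: pd.DataFrame, seed, config: SimConfig | None = None,
        variant_effects: pd.DataFrame | None = None,
        code_map: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the quantitative trait, accelerometer summaries with QC
    flags, and a long-format ICD-10 diagnosis table.

    The trait is ``covariate effects + sum(beta_sex * dosage) + N(0, sd)``;
    disease indicators are Bernoulli(logistic(alpha_g + slope * z)) where z
    is the standardized phenotype named by ``config.disease_phenotype``.
    Returns ``(phenotypes, diagnoses, variant_effects)``.
    """
    from .deciles import DEFAULT_CODE_MAP

    config = config or SimConfig()
    rng = _rng(seed)
    n = len(cohort)
    code_map = code_map or DEFAULT_CODE_MAP

    genetic = np.zeros(n)
    if genotypes is not None:
        if variant_effects is None:
            variant_effects = default_variant_effects(genotypes, config)
        male = (cohort["sex"] == "male").to_numpy()
        sample_pos = {s: j for j, s in enumerate(genotypes.samples)}
        missing = [p for p in cohort["participant_id"] if p not in sample_pos]
        if missing:
            raise ValueError(f"{len(missing)} participants missing from genotypes")
        cols = [sample_pos[p] for p in cohort["participant_id"]]
        for _, eff in variant_effects.iterrows():
            i = genotypes.index_of(eff["variant_id"])  # raises if absent
            dose = genotypes.dosages[i, cols]
            beta = np.where(male, eff["beta_male"], eff["beta_female"])
            genetic = genetic + beta * dose
    else:
        variant_effects = pd.DataFrame(columns=["variant_id", "beta_male",
                                                "beta_female"])

    age = cohort["age"].to_numpy()
    pheno = (config.pheno_age_effect * (age - age.mean())
             + config.pheno_sex_effect * (cohort["sex"] == "male").to_numpy()
             + config.pheno_ses_effect * cohort["ses"].to_numpy()
             + genetic
             + rng.normal(0.0, config.pheno_noise_sd, n))

    pa = rng.gamma(config.pa_shape, config.pa_mean / config.pa_shape, n)
    hi = rng.random(n) < config.pa_over100_prob
    pa = np.where(hi, rng.uniform(101.0, 150.0, n), pa)
    good_wear = rng.random(n) >= config.pa_bad_weartime_prob
    good_cal = rng.random(n) >= config.pa_bad_calibration_prob
    problems = np.where(rng.random(n) < config.pa_problem_prob,
                        "interrupted_recording", "")

    phenotypes = cohort[["participant_id"]].copy()
    phenotypes["pheno"] = pheno
    phenotypes["pa_accel_mg"] = pa
    phenotypes["good_wear_time"] = good_wear
    phenotypes["good_calibration"] = good_cal
    phenotypes["problem_indicators"] = problems

    # --- disease liability ---------------------------------------------------
    if config.disease_phenotype == "true_vo2max":
        driver = truth.set_index("participant_id").loc[
            cohort["participant_id"], "true_vo2max"].to_numpy()
    else:
        driver = pheno
    z = (driver - driver.mean()) / driver.std(ddof=0)
    rows: list[tuple[str, str]] = []
    pids = cohort["participant_id"].to_numpy()
    for group, base in config.disease_baseline.items():
        prefixes = code_map.get(group)
        if prefixes is None:
            continue
        alpha = np.log(base / (1.0 - base))
        p = 1.0 / (1.0 + np.exp(-(alpha + config.disease_slope * z)))
        sick = rng.random(n) < p
        for pid in pids[sick]:
            pref = rng.choice(prefixes)
            rows.append((pid, f"{pref}.{rng.integers(0, 10)}"))
            if rng.random() < 0.2:  # occasional repeat admission, same group
                pref2 = rng.choice(prefixes)
                rows.append((pid, f"{pref2}.{rng.integers(0, 10)}"))
    diagnoses = pd.DataFrame(rows, columns=["participant_id", "icd10_code"])
    return phenotypes, diagnoses, variant_effects
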