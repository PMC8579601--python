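"""Configuration objects for simulation and the end-to-end pipeline.

All tunables live in two dataclasses: :class:`SimConfig` (the synthetic
cohort generator) and :class:`PipelineConfig` (filter, association, clumping
and decile parameters plus the root seed).  Both round-trip losslessly
through YAML so a pipeline run is fully described by one config file.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["SimConfig", "PipelineConfig", "load_config", "save_config", "config_hash"]


def _d(**kw: Any):  # default factory helper for dict fields
    return field(default_factory=lambda: dict(kw))


@dataclass
class SimConfig:
    """Parameters of the synthetic biobank-style cohort generator.

    Units: ages in years, weight in kg, workload in W, heart rate in bpm,
    cadence in RPM, physical activity in milligravities (mg), durations in
    seconds, genomic positions in bp.
    """

    # --- cohort demographics -------------------------------------------------
    age_min: float = 40.0
    age_max: float = 69.0
    p_male: float = 0.5
    weight_mean_male: float = 85.0
    weight_mean_female: float = 70.0
    weight_sd: float = 14.0
    weight_min: float = 40.0
    ses_sd: float = 3.0                      # Townsend-like deprivation score
    n_centres: int = 6
    p_array_a: float = 0.9
    risk_frequencies: dict = _d(minimal=0.60, small=0.25, medium=0.10, high=0.05)
    smoking_probs: dict = _d(never=0.55, former=0.35, current=0.10)
    drinking_probs: dict = _d(never=0.10, former=0.10, current=0.80)

    # --- cardiorespiratory truth --------------------------------------------
    hr_rest_mean: float = 68.0
    hr_rest_sd: float = 8.0
    hr_rest_min: float = 45.0
    hr_rest_max: float = 95.0
    hr_per_watt_mean: float = 0.40           # bpm per W; lognormal, always > 0
    hr_per_watt_cv: float = 0.20

    # --- ramp-test protocol --------------------------------------------------
    sampling_interval_s: float = 4.0
    pretest_duration_s: float = 15.0
    exercise_duration_s: float = 360.0
    recovery_duration_s: float = 60.0
    constant_duration_s: float = 120.0       # lead-in before the 4-min ramp
    workload_start: dict = _d(minimal=40.0, small=30.0, medium=30.0)
    workload_ramp_height: dict = _d(minimal=90.0, small=60.0)

    # --- trace noise ---------------------------------------------------------
    hr_noise_sd: float = 3.0                 # AR(1) innovation scale, bpm
    hr_noise_rho: float = 0.6
    spike_prob: float = 0.01
    spike_amplitude: float = 30.0
    cadence_mean: float = 60.0
    cadence_sd: float = 5.0
    cadence_outlier_prob: float = 0.02

    # --- genotypes -----------------------------------------------------------
    maf_range: tuple = (0.05, 0.5)
    copy_prob: float = 0.9                   # haplotype-copying LD parameter
    within_block_spacing_bp: int = 5_000
    between_block_gap_bp: int = 300_000
    n_chromosomes: int = 22

    # --- phenotypes and outcomes --------------------------------------------
    pheno_noise_sd: float = 1.0
    pheno_age_effect: float = -0.02          # per year, on the genetic trait
    pheno_sex_effect: float = 0.3            # male minus female
    pheno_ses_effect: float = -0.05
    causal_beta_shared: float = 0.25         # SD units of the genetic trait
    causal_beta_male_only: float = 0.3
    causal_beta_female_only: float = 0.2
    pa_mean: float = 28.0
    pa_shape: float = 4.0                    # gamma shape of the PA summary
    pa_over100_prob: float = 0.01
    pa_bad_weartime_prob: float = 0.03
    pa_bad_calibration_prob: float = 0.02
    pa_problem_prob: float = 0.01
    disease_slope: float = -0.5              # log-odds per SD of phenotype
    disease_phenotype: str = "true_vo2max"
    disease_baseline: dict = _d(
        CAD=0.06, STR=0.012, ALZ=0.003, LCX=0.005, COPD=0.012,
        LRTI=0.020, CCX=0.010, DIA=0.035, KID=0.012, BCX=0.020,
    )

    def validate(self) -> None:
        if not (self.age_min < self.age_max):
            raise ValueError("age_min must be < age_max")
        if abs(sum(self.risk_frequencies.values()) - 1.0) > 1e-9:
            raise ValueError("risk_frequencies must sum to 1")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("maf_range must be a sub-interval of (0, 0.5]")
        for probs in (self.smoking_probs, self.drinking_probs):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("category probabilities must sum to 1")
        if not 0.0 <= self.copy_prob <= 1.0:
            raise ValueError("copy_prob must be in [0, 1]")


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters: simulation scale, QC thresholds,
    association/clumping settings and the root seed."""

    seed: int = 1
    n_participants: int = 2000
    n_variants: int = 500
    n_blocks: int = 50
    outdir: str = "ergogwas_out"
    sim: SimConfig = field(default_factory=SimConfig)

    # ramp-test QC / signal processing
    butter_order: int = 4
    butter_cutoff: float = 0.1               # fraction of Nyquist
    cadence_min: float = 35.0
    cadence_max: float = 125.0
    min_observations: int = 20
    vo2max_mode: str = "regression"          # or "endpoints"

    # physical activity QC
    pa_threshold_mg: float = 100.0

    # association / clumping
    p_threshold: float = 5e-8
    clump_r2: float = 0.2
    clump_window_kb: float = 500.0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in ("butter_cutoff", "pa_threshold_mg", "p_threshold",
                     "clump_r2", "clump_window_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.vo2max_mode not in ("regression", "endpoints"):
            raise ValueError("vo2max_mode must be 'regression' or 'endpoints'")
        self.sim.validate()


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return pipeline_config_from_dict(data)


def sim_config_from_dict(data: dict) -> SimConfig:
    cfg = SimConfig(**data)
    cfg.maf_range = tuple(cfg.maf_range)
    return cfg


def pipeline_config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data)
    sim = data.pop("sim", {})
    cfg = PipelineConfig(**data, sim=sim_config_from_dict(dict(sim)))
    return cfg


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash identifying a configuration (stamped on outputs).

    The output directory is not part of the hash: two runs of the same
    scientific configuration hash identically wherever they are written.
    """
    plain = _to_plain(config)
    plain.pop("outdir", None)
    blob = yaml.safe_dump(plain, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
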