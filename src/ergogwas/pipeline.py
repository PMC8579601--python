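"""End-to-end pipeline driver.

Stages run in dependency order::

    simulate -> crf / pa-qc -> residualize -> assoc (by stratum) -> clump
             -> het -> deciles

All randomness flows from the single root seed through named per-stage
child streams, so each stage is independently reproducible.  The manifest
records seeds, the config hash, per-stage row counts and input file hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity, assoc, clump, deciles, ergo, hetmeta, pheno, synthetic
from .config import PipelineConfig, config_hash, save_config
from .io import write_table, write_traces

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "stage_seed"]

STAGE_STREAMS = {"cohort": 0, "traces": 1, "genotypes": 2, "phenotypes": 3}


def stage_seed(root_seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(root_seed), STAGE_STREAMS[stage]])


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to
    ``outdir/manifest.json``)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    save_config(config, outdir / "config.yaml")
    manifest: dict = {"config_hash": chash, "seed": config.seed, "stages": {}}

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        log.info("stage %s: %s", stage, counts)

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    sim = config.sim
    # ------------------------------------------------------------- simulate
    try:
        cohort, truth = synthetic.simulate_cohort(
            config.n_participants, np.random.default_rng(stage_seed(config.seed, "cohort")), sim)
        traces = synthetic.simulate_traces(
            cohort, truth, stage_seed(config.seed, "traces"), sim)
        geno = synthetic.simulate_genotypes(
            len(cohort), config.n_variants, config.n_blocks, sim.maf_range,
            np.random.default_rng(stage_seed(config.seed, "genotypes")),
            copy_prob=sim.copy_prob,
            sample_ids=list(cohort["participant_id"]), config=sim)
        phenos, diagnoses, effects = synthetic.simulate_phenotypes_and_outcomes(
            cohort, geno, truth,
            np.random.default_rng(stage_seed(config.seed, "phenotypes")), sim)
    except Exception as exc:                                 # noqa: BLE001
        fail("simulate", exc)

    write_table(cohort, outdir / "cohort.tsv", stage="simulate", config_hash=chash)
    write_traces(traces, outdir / "traces.tsv", stage="simulate", config_hash=chash)
    write_table(phenos, outdir / "pa.tsv", stage="simulate", config_hash=chash)
    write_table(diagnoses, outdir / "diagnoses.tsv", stage="simulate",
                config_hash=chash)
    geno.to_vcf(outdir / "genotypes.vcf")
    geno.to_dosage_tsv(outdir / "genotypes.tsv")
    truth_sidecar = {
        "participants": truth.to_dict(orient="list"),
        "variant_effects": effects.to_dict(orient="list"),
        "disease_slope": sim.disease_slope,
        "disease_phenotype": sim.disease_phenotype,
    }
    (outdir / "truth.json").write_text(json.dumps(truth_sidecar))
    record("simulate", n_participants=len(cohort), n_trace_rows=len(traces),
           n_variants=geno.n_variants, n_diagnoses=len(diagnoses))

    # ------------------------------------------------------------------ crf
    try:
        sessions = ergo.sessions_from_traces(traces, cohort)
        crf, crf_excl = ergo.derive_crf_phenotypes(
            sessions, butter_order=config.butter_order,
            butter_cutoff=config.butter_cutoff, cadence_min=config.cadence_min,
            cadence_max=config.cadence_max,
            min_observations=config.min_observations, mode=config.vo2max_mode)
    except Exception as exc:                                 # noqa: BLE001
        fail("crf", exc)
    write_table(crf, outdir / "crf.tsv", stage="crf", config_hash=chash)
    write_table(crf_excl, outdir / "crf_exclusions.tsv", stage="crf",
                config_hash=chash)
    record("crf", n_records=len(crf), n_excluded=int(crf_excl["n"].sum())
           if len(crf_excl) else 0)

    # ---------------------------------------------------------------- pa-qc
    try:
        pa_qc, pa_log = activity.qc_pa(phenos, config.pa_threshold_mg)
    except Exception as exc:                                 # noqa: BLE001
        fail("pa-qc", exc)
    write_table(pa_qc, outdir / "pa_qc.tsv", stage="pa-qc", config_hash=chash)
    write_table(pa_log, outdir / "pa_exclusions.tsv", stage="pa-qc",
                config_hash=chash)
    record("pa-qc", n_included=int(pa_qc["included"].sum()),
           n_excluded=int((~pa_qc["included"]).sum()))

    # ----------------------------------------------------------- residualize
    try:
        merged = cohort.merge(phenos[["participant_id", "pheno"]],
                              on="participant_id")
        resid = {}
        for stratum in ("combined", "male", "female"):
            sub = merged if stratum == "combined" else \
                merged[merged["sex"] == stratum]
            spec = pheno.gwas_spec(include_sex=(stratum == "combined"))
            resid[stratum] = pheno.residualize(sub["pheno"], sub, spec)
        crf_cov = cohort.merge(crf[["participant_id", "crf_vo2max"]],
                               on="participant_id")
        decile_resid = {
            s: pheno.residualize(
                crf_cov.loc[crf_cov["sex"] == s, "crf_vo2max"],
                crf_cov[crf_cov["sex"] == s], pheno.decile_spec())
            for s in ("male", "female")
            if (crf_cov["sex"] == s).sum() >= 10
        }
    except Exception as exc:                                 # noqa: BLE001
        fail("residualize", exc)
    record("residualize", **{f"n_{k}": len(v) for k, v in resid.items()})

    # ---------------------------------------------------------------- assoc
    try:
        sumstats = {s: assoc.run_assoc(resid[s], geno, s, config.p_threshold)
                    for s in ("combined", "male", "female")}
    except Exception as exc:                                 # noqa: BLE001
        fail("assoc", exc)
    for s, tab in sumstats.items():
        write_table(tab, outdir / f"assoc_{s}.tsv", stage="assoc",
                    config_hash=chash)
    record("assoc", **{f"n_sig_{s}": int(t["genome_wide_significant"].sum())
                       for s, t in sumstats.items()})

    # ---------------------------------------------------------------- clump
    try:
        clumps, missing = clump.greedy_clump(
            sumstats["combined"], geno, config.p_threshold, config.clump_r2,
            config.clump_window_kb)
    except Exception as exc:                                 # noqa: BLE001
        fail("clump", exc)
    write_table(clump.clumps_to_table(clumps), outdir / "clumps.tsv",
                stage="clump", config_hash=chash)
    record("clump", n_clumps=len(clumps), n_missing_from_reference=len(missing))

    # ------------------------------------------------------------------ het
    try:
        index_ids = [c.index_variant for c in clumps]
        het = hetmeta.het_table(sumstats["male"], sumstats["female"],
                                variant_ids=index_ids or None,
                                n_snps_tested=max(len(index_ids), 1))
    except Exception as exc:                                 # noqa: BLE001
        fail("het", exc)
    write_table(het, outdir / "het.tsv", stage="het", config_hash=chash)
    record("het", n_variants=len(het))

    # -------------------------------------------------------------- deciles
    try:
        parts = []
        sex_map = cohort.set_index("participant_id")["sex"]
        for s, res in decile_resid.items():
            if len(res) >= 10:
                dec = deciles.assign_deciles(res)
                parts.append(deciles.disease_frequency(
                    dec, sex_map.loc[dec.index], diagnoses))
        decile_table = pd.concat(parts, ignore_index=True) if parts else \
            pd.DataFrame()
    except Exception as exc:                                 # noqa: BLE001
        fail("deciles", exc)
    write_table(decile_table, outdir / "decile_frequency.tsv", stage="deciles",
                config_hash=chash)
    record("deciles", n_rows=len(decile_table))

    manifest["input_hashes"] = {
        p.name: _file_hash(p) for p in sorted(outdir.glob("*.tsv"))
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
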