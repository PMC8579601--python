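"""Per-variant association of residualized traits.

Simple linear regression of the pre-residualized trait on allele dosage,
one variant at a time (vectorized).  With an unrelated cohort the
pre-residualized ordinary-least-squares fit is the natural stand-in for a
mixed-model association.  P-values use the t reference with n − 2 degrees
of freedom; effect sizes are oriented to the a1 (ALT/effect) allele, and
the conventional genome-wide significance threshold is p < 5e-8.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

__all__ = ["run_assoc", "GENOME_WIDE_P"]

GENOME_WIDE_P = 5e-8

SUMSTAT_COLUMNS = ["stratum", "chrom", "pos", "variant_id", "a1", "a0",
                   "a1_freq", "beta", "se", "p", "n",
                   "genome_wide_significant", "monomorphic"]


def run_assoc(residuals: pd.Series, genotypes: GenotypeMatrix,
              stratum: str = "combined", p_threshold: float = GENOME_WIDE_P
              ) -> pd.DataFrame:
    """Associate a residualized trait with every variant.

    ``residuals`` must be indexed by participant_id; only samples present in
    both the residuals and the genotype matrix are used, and per-variant
    missing dosages are handled complete-case.  Monomorphic (zero dosage
    variance) variants are emitted with missing statistics and the
    ``monomorphic`` flag rather than dropped.
    """
    common = [s for s in genotypes.samples if s in residuals.index]
    if len(common) < 3:
        raise ValueError("fewer than 3 samples shared between residuals "
                         "and genotypes")
    geno = genotypes.subset_samples(common)
    y = residuals.loc[common].to_numpy(dtype=float)
    G = geno.dosages                                  # (m, n), NaN = missing

    valid = ~np.isnan(G)
    n_v = valid.sum(axis=1).astype(float)
    yv = np.where(valid, y[None, :], 0.0)
    Gv = np.where(valid, G, 0.0)

    g_mean = Gv.sum(axis=1) / n_v
    y_mean = yv.sum(axis=1) / n_v
    sxx = (Gv ** 2).sum(axis=1) - n_v * g_mean ** 2
    sxy = (Gv * yv).sum(axis=1) - n_v * g_mean * y_mean
    syy = (yv ** 2).sum(axis=1) - n_v * y_mean ** 2

    mono = sxx <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(mono, np.nan, sxy / sxx)
        rss = syy - beta * sxy
        dof = n_v - 2
        sigma2 = np.where(dof > 0, rss / np.maximum(dof, 1), np.nan)
        se = np.sqrt(np.maximum(sigma2, 0.0) / np.where(mono, np.nan, sxx))
        tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(dof, 1))

    out = geno.variants[["chrom", "pos", "variant_id", "a1", "a0"]].copy()
    out.insert(0, "stratum", stratum)
    out["a1_freq"] = g_mean / 2.0
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["n"] = n_v.astype(int)
    out["genome_wide_significant"] = p < p_threshold
    out["monomorphic"] = mono
    out.loc[mono, ["se", "p"]] = np.nan
    out.loc[mono, "genome_wide_significant"] = False
    return out[SUMSTAT_COLUMNS]
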