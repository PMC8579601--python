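"""Two-stratum (male/female) fixed-effect meta-analysis with heterogeneity
statistics.

For a variant with sex-specific effect estimates (beta_m, se_m) and
(beta_f, se_f), inverse-variance weights w = 1/se² give the pooled effect
and Cochran's Q::

    beta_pooled = sum(w * beta) / sum(w)
    Q           = sum(w * (beta - beta_pooled)**2)

Q is chi-square with df = k − 1 = 1 under homogeneity; for two strata it
reduces to (beta_m − beta_f)² / (se_m² + se_f²).  The share of effect-size
variability attributable to heterogeneity is I² = 100·max(0, (Q − df)/Q).

The 95% confidence interval for I² is the Higgins–Thompson test-based
interval on ln H, with H = sqrt(Q/df) and, for Q > k,
se(ln H) = ln(Q) / (2·(sqrt(2Q) − 1)); the bounds transform back through
I² = 100·(H² − 1)/H², truncated below at 0.  When Q <= k the interval is
not defined by this formula and is reported as absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["HetStat", "meta_two_groups", "i2_confidence_interval",
           "follow_up_flag", "het_table"]

K_STRATA = 2
DF = K_STRATA - 1


@dataclass
class HetStat:
    variant_id: str
    beta_m: float
    se_m: float
    beta_f: float
    se_f: float
    beta_pooled: float
    se_pooled: float
    Q: float
    df: int
    p_Q: float
    i2: float                       # percent
    i2_ci: tuple | None             # (lower %, upper %) or None


def meta_two_groups(beta_m: float, se_m: float, beta_f: float, se_f: float,
                    variant_id: str = "") -> HetStat:
    """Fixed-effect inverse-variance pooling of two strata with Cochran's Q,
    I² and the test-based I² confidence interval."""
    if se_m <= 0 or se_f <= 0:
        raise ValueError("standard errors must be positive")
    w = np.array([1.0 / se_m ** 2, 1.0 / se_f ** 2])
    b = np.array([beta_m, beta_f])
    beta_pooled = float(np.sum(w * b) / np.sum(w))
    se_pooled = float(np.sqrt(1.0 / np.sum(w)))
    Q = float(np.sum(w * (b - beta_pooled) ** 2))
    p_Q = float(stats.chi2.sf(Q, DF))
    i2 = 100.0 * max(0.0, (Q - DF) / Q) if Q > 0 else 0.0
    return HetStat(variant_id=variant_id, beta_m=beta_m, se_m=se_m,
                   beta_f=beta_f, se_f=se_f, beta_pooled=beta_pooled,
                   se_pooled=se_pooled, Q=Q, df=DF, p_Q=p_Q, i2=i2,
                   i2_ci=i2_confidence_interval(Q))


def i2_confidence_interval(Q: float, df: int = DF) -> tuple | None:
    """95% test-based CI for I² from (Q, df), for a two-stratum comparison.

    Returns ``(lower %, upper %)``, each truncated below at 0, or ``None``
    when Q <= k (= df + 1) where the ln H standard error is undefined.
    """
    k = df + 1
    if Q <= k:
        return None
    ln_h = 0.5 * np.log(Q / df)
    se_ln_h = 0.5 * np.log(Q) / (np.sqrt(2.0 * Q) - 1.0)
    z = stats.norm.ppf(0.975)

    def to_i2(lnh: float) -> float:
        h2 = np.exp(2.0 * lnh)
        return float(100.0 * max(0.0, (h2 - 1.0) / h2))

    return (to_i2(ln_h - z * se_ln_h), to_i2(ln_h + z * se_ln_h))


def follow_up_flag(p_other_sex, n_snps_tested: int):
    """Bonferroni follow-up in the opposite sex: significant when
    p < 0.05 / n_snps_tested (n = number of SNPs tested in the trait
    family)."""
    if n_snps_tested < 1:
        raise ValueError("n_snps_tested must be >= 1")
    return np.asarray(p_other_sex, dtype=float) < 0.05 / n_snps_tested


def het_table(male: pd.DataFrame, female: pd.DataFrame,
              variant_ids=None, n_snps_tested: int | None = None
              ) -> pd.DataFrame:
    """Heterogeneity statistics for variants present in both sex-stratified
    summary-statistic tables (optionally restricted to ``variant_ids``).

    Betas are assumed oriented to the same effect allele in both strata;
    rows with mismatched alleles are re-oriented by flipping the female
    beta when its a1/a0 are swapped relative to the male row.
    """
    m = male.set_index("variant_id")
    f = female.set_index("variant_id")
    ids = variant_ids if variant_ids is not None else \
        [v for v in m.index if v in f.index]
    rows = []
    for vid in ids:
        rm, rf = m.loc[vid], f.loc[vid]
        bf = float(rf["beta"])
        if {"a1", "a0"} <= set(m.columns) and rm["a1"] == rf["a0"] \
                and rm["a0"] == rf["a1"]:
            bf = -bf
        h = meta_two_groups(float(rm["beta"]), float(rm["se"]),
                            bf, float(rf["se"]), variant_id=vid)
        rows.append({
            "variant_id": vid, "beta_m": h.beta_m, "se_m": h.se_m,
            "beta_f": h.beta_f, "se_f": h.se_f,
            "beta_pooled": h.beta_pooled, "se_pooled": h.se_pooled,
            "Q": h.Q, "p_Q": h.p_Q, "i2_pct": h.i2,
            "i2_ci_low": h.i2_ci[0] if h.i2_ci else np.nan,
            "i2_ci_high": h.i2_ci[1] if h.i2_ci else np.nan,
        })
    out = pd.DataFrame(rows)
    if n_snps_tested is not None and len(out):
        pm = m.loc[out["variant_id"], "p"].to_numpy(dtype=float)
        pf = f.loc[out["variant_id"], "p"].to_numpy(dtype=float)
        # follow-up of each sex's signal in the other sex
        out["male_sig_in_female"] = follow_up_flag(pf, n_snps_tested)
        out["female_sig_in_male"] = follow_up_flag(pm, n_snps_tested)
    return out
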