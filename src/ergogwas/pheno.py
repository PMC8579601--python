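"""Covariate residualization and descriptive summaries.

Association tests run on the residual of each trait regressed on a covariate
set.  Two conventions are shipped as presets:

* **gwas**: age, age², sex (sex-combined analyses only), genotyping array,
  assessment centre and the first 10 principal components; for ramp-test CRF
  traits additionally the protocol risk category and the number of trend
  entries.
* **decile**: age and socioeconomic status only (used for the disease
  frequency-by-decile analysis).

Smoking and drinking status are deliberately not part of either preset
(adjusting for heritable covariates can bias genetic effect estimates);
they can be added through ``extra`` for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CovariateSpec", "gwas_spec", "decile_spec", "build_design",
           "residualize", "descriptive_summary"]


@dataclass
class CovariateSpec:
    """Covariate columns and transforms defining a design matrix.

    ``numeric`` enter as-is, ``squared`` add a squared copy of a numeric
    column, ``categorical`` are expanded to drop-first indicator contrasts.
    """

    numeric: list = field(default_factory=list)
    squared: list = field(default_factory=list)
    categorical: list = field(default_factory=list)


def gwas_spec(include_sex: bool = True, crf: bool = False,
              extra: CovariateSpec | None = None) -> CovariateSpec:
    spec = CovariateSpec(
        numeric=["age"] + [f"pc{i}" for i in range(1, 11)],
        squared=["age"],
        categorical=(["sex"] if include_sex else []) + ["array", "centre"],
    )
    if crf:
        spec.categorical.append("risk_category")
        spec.numeric.append("n_trend")
    if extra:
        spec.numeric += extra.numeric
        spec.squared += extra.squared
        spec.categorical += extra.categorical
    return spec


def decile_spec() -> CovariateSpec:
    return CovariateSpec(numeric=["age", "ses"])


def build_design(table: pd.DataFrame, spec: CovariateSpec
                 ) -> tuple[np.ndarray, list]:
    """Build the intercept-augmented design matrix; raises on rank
    deficiency, naming the offending columns."""
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(table))}
    for c in spec.numeric:
        cols[c] = table[c].to_numpy(dtype=float)
    for c in spec.squared:
        cols[f"{c}^2"] = table[c].to_numpy(dtype=float) ** 2
    for c in spec.categorical:
        dummies = pd.get_dummies(table[c].astype(str), prefix=c, drop_first=True)
        for name in dummies.columns:
            cols[name] = dummies[name].to_numpy(dtype=float)
    names = list(cols)
    X = np.column_stack([cols[n] for n in names])
    # QR rank check: near-zero diagonal of R names the collinear columns
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    bad = [names[i] for i in range(len(names))
           if diag[i] < 1e-8 * max(1.0, diag.max())]
    if bad:
        raise ValueError(f"design matrix rank-deficient; collinear columns: {bad}")
    return X, names


def residualize(trait: pd.Series, table: pd.DataFrame, spec: CovariateSpec
                ) -> pd.Series:
    """Residual of ``trait`` regressed on the covariate design.

    Rows with a missing trait or covariate value are dropped (complete-case);
    the returned Series is indexed by ``participant_id`` of the retained
    rows.  Residuals are orthogonal to every design column and have mean
    ~0 by construction.
    """
    used = (list(dict.fromkeys(spec.numeric + spec.squared)) + spec.categorical)
    df = table.copy()
    df["_trait"] = np.asarray(trait, dtype=float)
    complete = df.dropna(subset=used + ["_trait"])
    X, _ = build_design(complete, spec)
    y = complete["_trait"].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return pd.Series(resid, index=pd.Index(complete["participant_id"],
                                           name="participant_id"),
                     name=getattr(trait, "name", "resid"))


def descriptive_summary(table: pd.DataFrame, columns: list,
                        by_sex: bool = False
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Means/SDs and pairwise Pearson correlations with p-values.

    Returns ``(summary, correlations)``; correlations of a zero-variance
    column are reported as missing.  At least 3 complete pairs are required
    per correlation.
    """
    groups = table.groupby("sex") if by_sex else [("all", table)]
    sum_rows, cor_rows = [], []
    for sex, sub in groups:
        for c in columns:
            vals = sub[c].dropna()
            sum_rows.append({"sex": sex, "variable": c, "n": len(vals),
                             "mean": vals.mean(), "sd": vals.std(ddof=1)})
        for i, a in enumerate(columns):
            for b_ in columns[i:]:
                if a == b_:
                    vals = sub[a].dropna()
                    r, p = (1.0, 0.0) if vals.std(ddof=0) > 0 \
                        else (np.nan, np.nan)
                    n_pair = len(vals)
                else:
                    pair = sub[[a, b_]].dropna()
                    n_pair = len(pair)
                    if n_pair < 3 or pair[a].std(ddof=0) == 0 \
                            or pair[b_].std(ddof=0) == 0:
                        r, p = np.nan, np.nan
                    else:
                        r, p = stats.pearsonr(pair[a], pair[b_])
                cor_rows.append({"sex": sex, "var1": a, "var2": b_,
                                 "n": n_pair, "r": r, "p": p})
    return pd.DataFrame(sum_rows), pd.DataFrame(cor_rows)
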