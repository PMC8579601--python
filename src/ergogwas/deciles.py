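"""Disease frequency by phenotype decile.

Participants are ranked on an age/SES-residualized phenotype separately in
males and females, split into ten approximately equal groups (sizes differ
by at most one), and the proportion with a main or secondary ICD-10
diagnosis in each disease group is computed per decile.  A participant
counts at most once per disease group regardless of repeat admissions;
participants with no diagnosis rows still count in the denominators.
Incident and prevalent disease are not distinguished, and ICD-9 records are
out of scope.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["DEFAULT_CODE_MAP", "assign_deciles", "disease_frequency"]


def _codes(prefix: str, lo: int, hi: int) -> list[str]:
    return [f"{prefix}{i:02d}" for i in range(lo, hi + 1)]


# Ten leading global causes of death in high-income countries, as ICD-10
# three-character prefix groups (matching is by string prefix).
DEFAULT_CODE_MAP: dict[str, list[str]] = {
    "CAD": _codes("I", 20, 25),                    # ischaemic heart disease
    "STR": _codes("I", 60, 69),                    # stroke
    "ALZ": ["F01", "F03", "G30"],                  # dementias incl. Alzheimer's
    "LCX": ["C33", "C34"],                         # trachea/bronchus/lung cancer
    "COPD": _codes("J", 40, 44) + ["J47"],         # chronic obstructive pulmonary
    "LRTI": _codes("J", 9, 18) + ["J20", "J21", "J22"],  # lower resp. infections
    "CCX": _codes("C", 18, 21),                    # colorectal cancers
    "DIA": _codes("E", 10, 14),                    # diabetes mellitus
    "KID": _codes("N", 0, 19),                     # kidney diseases
    "BCX": ["C50"],                                # breast cancer
}


def load_code_map(path) -> dict[str, list[str]]:
    """Read a disease-group -> ICD-10 prefix list mapping from a two-column
    TSV (group, comma-separated prefixes)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return {row.iloc[0]: [p.strip() for p in str(row.iloc[1]).split(",")]
            for _, row in df.iterrows()}


def assign_deciles(residuals: pd.Series, n_groups: int = 10) -> pd.Series:
    """Rank-based split into ``n_groups`` approximately equal groups.

    ``residuals`` must be indexed by participant_id (call once per sex
    stratum).  Ties in the phenotype are broken by participant_id, so the
    assignment is deterministic and independent of input order.  Group
    labels run 1 (lowest phenotype) to ``n_groups``; sizes are floor(n/10)
    or ceil(n/10).
    """
    n = len(residuals)
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} participants, got {n}")
    order = sorted(residuals.index, key=lambda pid: (residuals[pid], pid))
    labels = pd.Series(0, index=residuals.index, name="decile")
    for g, chunk in enumerate(np.array_split(np.asarray(order, dtype=object),
                                             n_groups), start=1):
        labels[chunk] = g
    return labels


def disease_frequency(deciles: pd.Series, sex: pd.Series,
                      diagnoses: pd.DataFrame,
                      code_map: dict[str, list[str]] | None = None,
                      n_groups: int = 10) -> pd.DataFrame:
    """Per-sex, per-disease-group diagnosis frequency by decile.

    ``deciles`` and ``sex`` are participant-indexed Series covering the same
    participants; ``diagnoses`` is long format (participant_id, icd10_code).
    Diagnosis codes matching no group are ignored (count logged).
    Frequencies are n_diagnosed / n_in_decile in [0, 1].
    """
    code_map = code_map or DEFAULT_CODE_MAP
    frame = pd.DataFrame({"decile": deciles, "sex": sex}).dropna()

    dx = diagnoses[diagnoses["participant_id"].isin(frame.index)]
    matched = np.zeros(len(dx), dtype=bool)
    group_members: dict[str, set] = {}
    codes = dx["icd10_code"].astype(str)
    for group, prefixes in code_map.items():
        hit = np.zeros(len(dx), dtype=bool)
        for pref in prefixes:
            hit |= codes.str.startswith(pref).to_numpy()
        matched |= hit
        group_members[group] = set(dx.loc[hit, "participant_id"])
    n_unmapped = int((~matched).sum())
    if n_unmapped:
        log.warning("%d diagnosis rows matched no disease group", n_unmapped)

    rows = []
    for sex_level, sub in frame.groupby("sex"):
        for group in code_map:
            diagnosed = group_members.get(group, set())
            for dec in range(1, n_groups + 1):
                members = sub.index[sub["decile"] == dec]
                n_in = len(members)
                n_dx = sum(1 for p in members if p in diagnosed)
                rows.append({"sex": sex_level, "disease_group": group,
                             "decile": dec, "n_in_decile": n_in,
                             "n_diagnosed": n_dx,
                             "frequency": n_dx / n_in if n_in else np.nan})
    return pd.DataFrame(rows)
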