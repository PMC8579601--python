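"""P-value-informed LD clumping of association results.

Significant variants (p below the genome-wide threshold) are grouped into
independent signals: iterating in ascending p, the best unassigned variant
seeds a clump and absorbs every unassigned variant on the same chromosome
within the window whose squared dosage correlation with it reaches the r²
threshold (defaults: r² >= 0.2 within +/-500 kb, the PLINK convention).
Ties in p are broken by (chrom, pos, variant_id) so the partition is
deterministic and independent of input row order.  Variants absent from the
LD reference genotypes cannot be clumped and are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["Clump", "ld_r2", "greedy_clump"]


@dataclass
class Clump:
    index_variant: str
    chrom: str
    index_p: float
    members: list          # (variant_id, r2 with index); includes the index
    span: tuple            # (min pos, max pos) over members

    @property
    def n_members(self) -> int:
        return len(self.members)


def ld_r2(genotypes: GenotypeMatrix, i: int | str, j: int | str) -> float:
    """Squared Pearson correlation of dosages between two variants
    (complete-case); NaN when either is monomorphic."""
    if isinstance(i, str):
        i = genotypes.index_of(i)
    if isinstance(j, str):
        j = genotypes.index_of(j)
    x, y = genotypes.dosages[i], genotypes.dosages[j]
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def greedy_clump(assoc: pd.DataFrame, genotypes: GenotypeMatrix,
                 p_threshold: float = 5e-8, r2_threshold: float = 0.2,
                 window_kb: float = 500.0
                 ) -> tuple[list[Clump], list[str]]:
    """Greedy p-value-informed clumping.

    Returns ``(clumps, missing)`` where ``missing`` lists significant
    variants absent from the reference genotypes (excluded from clumping).
    An empty result when nothing passes ``p_threshold`` is not an error.
    """
    known = set(genotypes.variants["variant_id"])
    sig = assoc[(assoc["p"] < p_threshold) & assoc["p"].notna()].copy()
    missing = sorted(set(sig["variant_id"]) - known)
    sig = sig[sig["variant_id"].isin(known)]
    sig = sig.sort_values(["p", "chrom", "pos", "variant_id"],
                          kind="mergesort").reset_index(drop=True)

    window_bp = window_kb * 1000.0
    unassigned = dict.fromkeys(sig["variant_id"])  # insertion = priority order
    rows = sig.set_index("variant_id")
    clumps: list[Clump] = []
    while unassigned:
        index_id = next(iter(unassigned))
        del unassigned[index_id]
        irow = rows.loc[index_id]
        members = [(index_id, 1.0)]
        for vid in list(unassigned):
            vrow = rows.loc[vid]
            if str(vrow["chrom"]) != str(irow["chrom"]):
                continue
            if abs(float(vrow["pos"]) - float(irow["pos"])) > window_bp:
                continue
            r2 = ld_r2(genotypes, index_id, vid)
            if np.isnan(r2) or r2 < r2_threshold:
                continue
            members.append((vid, r2))
            del unassigned[vid]
        positions = [int(rows.loc[v, "pos"]) for v, _ in members]
        clumps.append(Clump(index_variant=index_id, chrom=str(irow["chrom"]),
                            index_p=float(irow["p"]), members=members,
                            span=(min(positions), max(positions))))
    return clumps, missing


def clumps_to_table(clumps: list[Clump]) -> pd.DataFrame:
    return pd.DataFrame([{
        "index_variant": c.index_variant, "chrom": c.chrom,
        "index_p": c.index_p, "n_members": c.n_members,
        "span_start": c.span[0], "span_end": c.span[1],
        "members": ";".join(f"{v}:{r2:.3f}" for v, r2 in c.members),
    } for c in clumps])
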