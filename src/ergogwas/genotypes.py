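"""Genotype container and VCF / dosage-matrix I/O.

Genotypes are held as a dense variants x samples dosage matrix (values in
[0, 2], NaN = missing) with per-variant metadata (chrom, pos, id, alleles).
Files are exchanged either as a minimal VCF v4.2 with a DS (dosage) FORMAT
field, read back through cyvcf2, or as a plain dosage TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]

VARIANT_COLUMNS = ["chrom", "pos", "variant_id", "a1", "a0"]


@dataclass
class GenotypeMatrix:
    """Dense dosage matrix plus variant metadata and sample ids.

    ``dosages[i, j]`` is the a1 (effect allele) dosage of sample ``j`` at
    variant ``i``.  Positions are 1-based and strictly increasing within a
    chromosome.
    """

    dosages: np.ndarray               # (n_variants, n_samples) float64
    variants: pd.DataFrame            # columns VARIANT_COLUMNS
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValueError("dosage matrix shape does not match metadata")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < -1e-9 or \
               np.nanmax(self.dosages, initial=0.0) > 2.0 + 1e-9:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Per-variant a1 allele frequency (complete-case)."""
        return np.nanmean(self.dosages, axis=1) / 2.0

    def index_of(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in genotype matrix")
        return int(idx[0])

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        pos = {s: j for j, s in enumerate(self.samples)}
        cols = [pos[s] for s in sample_ids]
        return GenotypeMatrix(self.dosages[:, cols],
                              self.variants.reset_index(drop=True),
                              list(sample_ids))

    # ------------------------------------------------------------------ I/O
    def to_dosage_tsv(self, path: str | Path) -> None:
        meta = self.variants[VARIANT_COLUMNS].copy()
        dose = pd.DataFrame(self.dosages, columns=self.samples)
        pd.concat([meta.reset_index(drop=True), dose], axis=1).to_csv(
            path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_dosage_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", comment="#",
                         dtype={"chrom": str, "variant_id": str})
        meta = df[VARIANT_COLUMNS].copy()
        samples = [c for c in df.columns if c not in VARIANT_COLUMNS]
        return cls(df[samples].to_numpy(dtype=float), meta, samples)

    def to_vcf(self, path: str | Path) -> None:
        """Write a minimal VCF v4.2 with a DS FORMAT field."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                     'Description="Estimated alternate allele dosage">\n')
            for chrom in pd.unique(self.variants["chrom"]):
                sub = self.variants[self.variants["chrom"] == chrom]
                fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1000}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.samples) + "\n")
            for i, row in self.variants.iterrows():
                # REF = a0 (reference allele), ALT = a1 (effect allele, dosage counted)
                vals = "\t".join(
                    "." if np.isnan(d) else f"{d:.4g}" for d in self.dosages[i])
                fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{row['variant_id']}\t"
                         f"{row['a0']}\t{row['a1']}\t.\t.\t.\tDS\t{vals}\n")

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        """Read genotypes from VCF: DS field if present, else GT hard calls."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        meta, rows = [], []
        for var in vcf:
            try:
                ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
            except (KeyError, TypeError, ValueError):
                ds = None
            if ds is None:
                gts = np.asarray(var.gt_types, dtype=float)  # 0,1,2;3=missing
                gts[gts == 3] = np.nan
                # cyvcf2 codes HOM_ALT as 2 only via gt_types==3? use genotypes
                ds = np.array([np.nan if g[0] < 0 else float(g[0] + g[1])
                               for g in var.genotypes])
            rows.append(ds)
            meta.append((var.CHROM, var.POS, var.ID or f"{var.CHROM}:{var.POS}",
                         var.ALT[0] if var.ALT else ".", var.REF))
        variants = pd.DataFrame(meta, columns=VARIANT_COLUMNS)
        return cls(np.vstack(rows) if rows else np.empty((0, len(samples))),
                   variants, samples)
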