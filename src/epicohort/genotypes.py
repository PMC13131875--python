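"""Dosage-matrix container with variant metadata and text-format I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]

_VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "maf"]


@dataclass
class GenotypeMatrix:
    """Per-individual alternative-allele dosages (0/1/2).

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` integer array with entries in {0, 1, 2}.
    samples
        Sample identifiers, one per row.
    variants
        Metadata frame with columns ``id, chrom, pos, ref, alt, maf``.
    """

    dosages: np.ndarray
    samples: list[str]
    variants: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosage entries must be in {0, 1, 2}")
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample count does not match dosage rows")
        missing = [c for c in _VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant metadata missing columns: {missing}")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError("variant count does not match dosage columns")
        self.variants = self.variants.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Observed alternative-allele frequency per variant."""
        return self.dosages.mean(axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        unknown = [s for s in sample_ids if s not in index]
        if unknown:
            raise KeyError(f"unknown samples: {unknown[:5]}")
        rows = [index[s] for s in sample_ids]
        return GenotypeMatrix(self.dosages[rows], list(sample_ids), self.variants.copy())

    def subset_variants(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.arange(self.n_variants)[mask_or_idx]
        return GenotypeMatrix(
            self.dosages[:, idx], list(self.samples), self.variants.iloc[idx].copy()
        )

    # ------------------------------------------------------------------
    # text I/O
    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: variants as rows, one column per sample."""
        frame = self.variants[_VARIANT_COLUMNS].copy()
        body = pd.DataFrame(self.dosages.T, columns=self.samples)
        pd.concat([frame, body], axis=1).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        table = pd.read_csv(path, sep="\t")
        meta = table[_VARIANT_COLUMNS].copy()
        samples = [c for c in table.columns if c not in _VARIANT_COLUMNS]
        dosages = table[samples].to_numpy(dtype=np.int8).T
        return cls(dosages, samples, meta)

    def to_vcf(self, path: str | Path) -> None:
        """Write a minimal VCF 4.2 with GT genotypes (unphased)."""
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            for j, row in self.variants.iterrows():
                gts = "\t".join(gt_codes[int(d)] for d in self.dosages[:, j])
                fh.write(
                    f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t"
                    f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t{gts}\n"
                )

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        """Read GT dosages from a (plain-text) VCF via pysam."""
        import pysam

        records = []
        dosage_rows = []
        with pysam.VariantFile(str(path)) as vcf:
            samples = list(vcf.header.samples)
            for rec in vcf:
                alts = rec.alts or ("N",)
                records.append(
                    {
                        "id": rec.id or f"{rec.chrom}:{rec.pos}",
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": alts[0],
                        "maf": np.nan,
                    }
                )
                row = []
                for s in samples:
                    gt = rec.samples[s]["GT"]
                    row.append(sum(1 for a in gt if a not in (None, 0)))
                dosage_rows.append(row)
        dosages = np.asarray(dosage_rows, dtype=np.int8).T
        meta = pd.DataFrame(records)
        p = dosages.mean(axis=0) / 2.0
        meta["maf"] = np.minimum(p, 1 - p)
        return cls(dosages, samples, meta)
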