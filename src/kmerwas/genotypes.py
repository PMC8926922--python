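"""Biallelic genotype matrix shared by the QC and population-structure stages.

Call codes: 0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

_GT_TO_CODE = {
    (0, 0): HOM_REF,
    (0, 1): HET,
    (1, 0): HET,
    (1, 1): HOM_ALT,
    (None, None): MISSING,
}
_CODE_TO_GT = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Per-site biallelic calls across accessions.

    Positions are 1-based and strictly increasing within a chromosome.
    """

    chrom: np.ndarray  # (n_sites,) object/str
    pos: np.ndarray  # (n_sites,) int64, 1-based
    ref: np.ndarray  # (n_sites,) single-base str
    alt: np.ndarray  # (n_sites,) single-base str
    accessions: list[str]
    calls: np.ndarray  # (n_sites, n_accessions) int8

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise GenotypeError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def column(self, accession: str) -> np.ndarray:
        try:
            j = self.accessions.index(accession)
        except ValueError:
            raise GenotypeError(f"unknown accession {accession!r}") from None
        return self.calls[:, j]

    def subset_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.chrom[idx], self.pos[idx], self.ref[idx], self.alt[idx],
            list(self.accessions), self.calls[idx],
        )

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage (0/1/2) as float with NaN for missing."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    # --- VCF I/O -------------------------------------------------------

    def to_vcf(self, path: str | Path) -> None:
        """Minimal plain-text VCF with GT-only genotype fields."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in dict.fromkeys(self.chrom.tolist()):
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.accessions) + "\n"
            )
            for i in range(self.n_sites):
                gts = "\t".join(_CODE_TO_GT[int(c)] for c in self.calls[i])
                fh.write(
                    f"{self.chrom[i]}\t{self.pos[i]}\t.\t{self.ref[i]}\t{self.alt[i]}"
                    f"\t.\t.\t.\tGT\t{gts}\n"
                )

    @classmethod
    def from_vcf(cls, path: str | Path) -> tuple["GenotypeMatrix", int]:
        """Read biallelic SNV records; returns (matrix, n_skipped) where
        skipped counts multiallelic/non-SNV records."""
        import pysam

        skipped = 0
        chrom, pos, ref, alt, rows = [], [], [], [], []
        with pysam.VariantFile(str(path)) as vf:
            accessions = list(vf.header.samples)
            for rec in vf:
                if rec.alts is None or len(rec.alts) != 1:
                    skipped += 1
                    continue
                row = np.empty(len(accessions), dtype=np.int8)
                for j, s in enumerate(accessions):
                    gt = rec.samples[s].get("GT", (None, None))
                    row[j] = _GT_TO_CODE.get(tuple(gt), MISSING)
                chrom.append(rec.chrom)
                pos.append(rec.pos)
                ref.append(rec.ref)
                alt.append(rec.alts[0])
                rows.append(row)
        if not rows:
            mat = cls(
                np.empty(0, object), np.empty(0, np.int64),
                np.empty(0, object), np.empty(0, object),
                accessions, np.empty((0, len(accessions)), np.int8),
            )
            return mat, skipped
        return (
            cls(np.array(chrom, object), np.array(pos), np.array(ref, object),
                np.array(alt, object), accessions, np.vstack(rows)),
            skipped,
        )
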