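"""Synthetic diversity panels with known ground truth.

A panel of diploid accessions is drawn from three diverged lineages: each
lineage founder is derived from one random ancestor by an independent
substitution process (star phylogeny), and each accession from its founder
by a second, shallower process.  This creates lineage-private variation,
a realistic F_ST contrast and lineage-specific k-mers without any
demographic realism.

Every substitution at a position uses one deterministic alternative
allele, so all sites are guaranteed biallelic and the exact truth
genotype matrix can be reconstructed at any time.

Heterozygosity is represented in the genotype matrix only: each accession
carries a single consensus sequence (the alt allele at het sites), which
is what the k-mer stages consume.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .kmer_engine import codes_to_seq, seq_to_codes

LINEAGES = ("L1", "L2", "L3")


class ConfigError(ValueError):
    pass


def _alt_code(ref: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Deterministic alternative allele per (ref, position); never equals ref."""
    return (ref + 1 + (pos * np.int64(2654435761)) % 3).astype(np.uint8) % 4


@dataclass
class PanelConfig:
    n_per_lineage: tuple[int, int, int] = (5, 5, 5)
    genome_length: int = 100_000
    n_chromosomes: int = 1
    divergence: float = 0.01
    within_diversity: float = 0.002
    # optional hierarchical substructure: sub-founders inside each lineage,
    # giving the panel within-lineage relatedness axes (as real panels have)
    subpops_per_lineage: int = 1
    sub_divergence: float = 0.0
    het_fraction: float = 0.0
    seed: int = 0
    k: int = 51
    # causal haplotype (0 length = none planted)
    causal_length: int = 0
    causal_mut_rate: float = 0.01
    causal_effect: float = 0.0
    causal_carrier_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("divergence", "within_diversity", "het_fraction",
                     "causal_mut_rate", "causal_carrier_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.genome_length < 10 * self.k:
            raise ConfigError(
                f"genome_length {self.genome_length} < 10*k = {10 * self.k}"
            )
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        if self.subpops_per_lineage < 1:
            raise ConfigError("subpops_per_lineage must be >= 1")
        if not 0.0 <= self.sub_divergence <= 1.0:
            raise ConfigError("sub_divergence must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Generator ledger: everything downstream stages may be tested against."""

    lineage_of: dict[str, str] = field(default_factory=dict)
    causal_locus: tuple[str, int, int, float] | None = None  # chrom, 1-based start, end, effect
    carriers: list[str] = field(default_factory=list)
    duplicates: list[tuple[str, str]] = field(default_factory=list)
    mosaic_intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class AccessionRecord:
    accession_id: str
    lineage: str
    codes: dict[str, np.ndarray]  # chrom -> uint8 base codes
    het_sites: dict[str, np.ndarray]  # chrom -> sorted 0-based positions called het

    def sequences(self) -> dict[str, str]:
        return {c: codes_to_seq(v) for c, v in self.codes.items()}

    def sequence_list(self) -> list[str]:
        return [codes_to_seq(v) for v in self.codes.values()]


@dataclass
class Panel:
    config: PanelConfig
    ancestor: dict[str, np.ndarray]
    founders: dict[str, dict[str, np.ndarray]]  # lineage -> chrom -> codes
    accessions: list[AccessionRecord]
    truth: SyntheticTruth

    @property
    def accession_ids(self) -> list[str]:
        return [a.accession_id for a in self.accessions]

    def record(self, accession_id: str) -> AccessionRecord:
        for a in self.accessions:
            if a.accession_id == accession_id:
                return a
        raise KeyError(accession_id)

    def genotype_matrix(self) -> GenotypeMatrix:
        """Exact truth genotype matrix: one site per position at which any
        accession's consensus differs from the ancestor."""
        chroms, poss, refs, alts, call_rows = [], [], [], [], []
        for chrom, anc in self.ancestor.items():
            diff_pos = np.unique(np.concatenate(
                [np.flatnonzero(a.codes[chrom] != anc) for a in self.accessions]
                or [np.empty(0, dtype=np.int64)]
            )).astype(np.int64)
            if len(diff_pos) == 0:
                continue
            ref = anc[diff_pos]
            alt = _alt_code(ref, diff_pos)
            calls = np.zeros((len(diff_pos), len(self.accessions)), dtype=np.int8)
            for j, a in enumerate(self.accessions):
                is_alt = a.codes[chrom][diff_pos] != ref
                het = np.isin(diff_pos, a.het_sites.get(chrom, np.empty(0, np.int64)))
                calls[:, j] = np.where(is_alt, np.where(het, 1, 2), 0)
            chroms.append(np.full(len(diff_pos), chrom, dtype=object))
            poss.append(diff_pos + 1)
            refs.append(np.array(list(codes_to_seq(ref)), dtype=object))
            alts.append(np.array(list(codes_to_seq(alt)), dtype=object))
            call_rows.append(calls)
        if not chroms:
            n = len(self.accessions)
            return GenotypeMatrix(
                np.empty(0, object), np.empty(0, np.int64), np.empty(0, object),
                np.empty(0, object), self.accession_ids, np.empty((0, n), np.int8))
        return GenotypeMatrix(
            np.concatenate(chroms), np.concatenate(poss), np.concatenate(refs),
            np.concatenate(alts), self.accession_ids, np.vstack(call_rows))


def _chrom_lengths(total: int, n: int) -> list[int]:
    base = total // n
    lens = [base] * n
    lens[0] += total - base * n
    return lens


def _mutate(
    codes: np.ndarray, rate: float, rng: np.random.Generator,
    ancestor: np.ndarray | None = None,
) -> np.ndarray:
    """Per-site substitution; each site toggles between the ancestor base
    and its one deterministic alternative, keeping all sites biallelic."""
    out = codes.copy()
    if rate > 0:
        anc = codes if ancestor is None else ancestor
        pos = np.flatnonzero(rng.random(len(codes)) < rate)
        ref = anc[pos]
        out[pos] = np.where(codes[pos] == ref, _alt_code(ref, pos), ref)
    return out


def simulate_panel(config: PanelConfig) -> Panel:
    """Simulate the full panel; returns sequences, truth ledger and the
    truth genotype matrix (via :meth:`Panel.genotype_matrix`)."""
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    lengths = _chrom_lengths(config.genome_length, config.n_chromosomes)
    ancestor = {c: rng.integers(0, 4, size=l, dtype=np.uint8)
                for c, l in zip(chrom_names, lengths)}

    active = [lin for lin, n in zip(LINEAGES, config.n_per_lineage) if n > 0]
    founders: dict[str, dict[str, np.ndarray]] = {}
    for lin in active:
        founders[lin] = {c: _mutate(anc, config.divergence, rng)
                         for c, anc in ancestor.items()}

    # causal haplotype: a fixed mutated copy of the ancestor interval
    causal_chrom = chrom_names[0]
    causal_segment = None
    c_start = c_end = 0
    if config.causal_length > 0:
        L0 = lengths[0]
        if config.causal_length > L0:
            raise ConfigError("causal_length exceeds chromosome length")
        c_start = (L0 - config.causal_length) // 2
        c_end = c_start + config.causal_length
        seg_ref = ancestor[causal_chrom][c_start:c_end]
        seg_pos = np.arange(c_start, c_end, dtype=np.int64)
        hit = rng.random(config.causal_length) < config.causal_mut_rate
        hit[config.causal_length // 2] = True  # at least one causal site
        causal_segment = seg_ref.copy()
        causal_segment[hit] = _alt_code(seg_ref[hit], seg_pos[hit])

    sub_founders: dict[str, list[dict[str, np.ndarray]]] = {}
    for lin in active:
        if config.subpops_per_lineage > 1 and config.sub_divergence > 0:
            sub_founders[lin] = [
                {c: _mutate(f, config.sub_divergence, rng, ancestor[c])
                 for c, f in founders[lin].items()}
                for _ in range(config.subpops_per_lineage)
            ]
        else:
            sub_founders[lin] = [founders[lin]]

    truth = SyntheticTruth()
    accessions: list[AccessionRecord] = []
    for lin, n in zip(LINEAGES, config.n_per_lineage):
        for i in range(n):
            aid = f"{lin}_{i:03d}"
            base = sub_founders[lin][i % len(sub_founders[lin])]
            codes = {c: _mutate(f, config.within_diversity, rng, ancestor[c])
                     for c, f in base.items()}
            accessions.append(AccessionRecord(aid, lin, codes, {}))
            truth.lineage_of[aid] = lin

    if causal_segment is not None:
        n_total = len(accessions)
        n_carriers = min(max(1, round(config.causal_carrier_fraction * n_total)),
                         n_total - 1)
        carrier_idx = rng.choice(n_total, size=n_carriers, replace=False)
        for j in sorted(carrier_idx):
            accessions[j].codes[causal_chrom][c_start:c_end] = causal_segment
            truth.carriers.append(accessions[j].accession_id)
        truth.causal_locus = (causal_chrom, c_start + 1, c_end, config.causal_effect)

    if config.het_fraction > 0:
        for a in accessions:
            for chrom, anc in ancestor.items():
                var = np.flatnonzero(a.codes[chrom] != anc)
                if len(var):
                    het = var[rng.random(len(var)) < config.het_fraction]
                    a.het_sites[chrom] = het

    return Panel(config, ancestor, founders, accessions, truth)


def simulate_phenotype(
    truth: SyntheticTruth,
    accession_ids: Sequence[str],
    carriers: Iterable[str] | None = None,
    effect: float | None = None,
    lineage_shift: Mapping[str, float] | None = None,
    noise_sd: float = 1.0,
    seed: int | None = None,
    baseline: float = 10.0,
) -> pd.Series:
    """phenotype = baseline + effect * carrier + lineage_shift + N(0, noise_sd)."""
    if noise_sd < 0:
        raise ConfigError(f"noise_sd must be >= 0, got {noise_sd}")
    carriers = set(truth.carriers if carriers is None else carriers)
    unknown = carriers - set(accession_ids)
    if unknown:
        raise ConfigError(f"carriers not in panel: {sorted(unknown)}")
    if effect is None:
        effect = truth.causal_locus[3] if truth.causal_locus else 0.0
    rng = np.random.default_rng(seed)
    vals = []
    for aid in accession_ids:
        y = baseline + (effect if aid in carriers else 0.0)
        if lineage_shift:
            y += lineage_shift.get(truth.lineage_of.get(aid, ""), 0.0)
        vals.append(y)
    noise = rng.normal(0.0, noise_sd, size=len(vals)) if noise_sd > 0 else 0.0
    return pd.Series(np.asarray(vals) + noise, index=list(accession_ids), name="phenotype")


def shred_reads(
    sequences: Mapping[str, str] | Sequence[str],
    fold_coverage: float,
    read_length: int,
    seed: int | None = None,
    k: int | None = None,
    error_rate: float = 0.0,
) -> list[str]:
    """Error-free uniform reads totalling ~fold_coverage x genome length
    (within one read; at least one read is always emitted).  Reads come
    from either strand.  ``error_rate`` optionally substitutes bases."""
    if fold_coverage <= 0:
        raise ConfigError("fold_coverage must be > 0")
    if k is not None and read_length < k:
        raise ConfigError(f"read_length {read_length} < k {k}")
    seqs = list(sequences.values()) if isinstance(sequences, Mapping) else list(sequences)
    codes = [seq_to_codes(s) if isinstance(s, str) else s for s in seqs]
    lens = np.array([len(c) for c in codes], dtype=float)
    total = lens.sum()
    n_reads = max(1, math.ceil(fold_coverage * total / read_length))
    rng = np.random.default_rng(seed)
    which = rng.choice(len(codes), size=n_reads, p=lens / total) if len(codes) > 1 \
        else np.zeros(n_reads, dtype=int)
    reads: list[str] = []
    for idx in which:
        src = codes[idx]
        if len(src) <= read_length:
            frag = src.copy()
        else:
            start = rng.integers(0, len(src) - read_length + 1)
            frag = src[start:start + read_length].copy()
        if error_rate > 0:
            pos = np.flatnonzero(rng.random(len(frag)) < error_rate)
            frag[pos] = (frag[pos] + rng.integers(1, 4, size=len(pos))) % 4
        if rng.random() < 0.5:
            frag = (3 - frag)[::-1]
        reads.append(codes_to_seq(frag))
    return reads


def make_mosaic(
    donors: Mapping[str, str],
    segment_plan: Sequence[tuple[int, str]],
    chrom: str = "mosaic",
) -> tuple[str, list[tuple[str, int, int, str]]]:
    """Concatenate donor segments (copied at the mosaic's own coordinates)
    into one chromosome.  Returns the mosaic sequence and truth intervals
    as (chrom, 1-based start, end inclusive, donor lineage)."""
    parts: list[str] = []
    intervals: list[tuple[str, int, int, str]] = []
    offset = 0
    for length, lineage in segment_plan:
        if lineage not in donors:
            raise ConfigError(f"no donor sequence for lineage {lineage!r}")
        donor = donors[lineage]
        if offset + length > len(donor):
            raise ConfigError(
                f"plan needs {offset + length} bases of {lineage} donor, "
                f"have {len(donor)}"
            )
        parts.append(donor[offset:offset + length])
        intervals.append((chrom, offset + 1, offset + length, lineage))
        offset += length
    return "".join(parts), intervals


def clone_with_noise(
    panel: Panel,
    accession_id: str,
    mismatch_rate: float,
    seed: int | None = None,
    clone_id: str | None = None,
) -> AccessionRecord:
    """Append a near-identical copy of an accession (per-site substitution
    at ``mismatch_rate``) and register the pair in the truth ledger."""
    if not 0.0 <= mismatch_rate < 1.0:
        raise ConfigError(f"mismatch_rate must be in [0, 1), got {mismatch_rate}")
    src = panel.record(accession_id)
    clone_id = clone_id or f"{accession_id}_dup"
    rng = np.random.default_rng(seed)
    codes: dict[str, np.ndarray] = {}
    for chrom, c in src.codes.items():
        out = c.copy()
        pos = np.flatnonzero(rng.random(len(c)) < mismatch_rate)
        if len(pos):
            anc = panel.ancestor[chrom][pos]
            # flip towards the biallelic alternative: ref->alt, alt->ref
            out[pos] = np.where(c[pos] == anc, _alt_code(anc, pos), anc)
        codes[chrom] = out
    clone = AccessionRecord(clone_id, src.lineage,
                            codes, {c: v.copy() for c, v in src.het_sites.items()})
    panel.accessions.append(clone)
    panel.truth.lineage_of[clone_id] = src.lineage
    panel.truth.duplicates.append((accession_id, clone_id))
    return clone


# --- writers ------------------------------------------------------------


def write_fasta(path: str | Path, records: Mapping[str, str], wrap: int = 60) -> None:
    """Uppercase, 60-column-wrapped multi-record FASTA."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            seq = seq.upper()
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")


def write_panel_fastas(panel: Panel, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for a in panel.accessions:
        p = outdir / f"{a.accession_id}.fasta"
        write_fasta(p, a.sequences())
        paths.append(p)
    return paths


def write_phenotypes(path: str | Path, phenotypes: pd.Series) -> None:
    phenotypes.rename("value").rename_axis("accession_id").to_csv(path, sep="\t")


def read_phenotypes(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="phenotype")


def write_lineages(path: str | Path, truth: SyntheticTruth) -> None:
    with open(path, "w") as fh:
        fh.write("accession_id\tlineage\n")
        for aid, lin in truth.lineage_of.items():
            fh.write(f"{aid}\t{lin}\n")


def read_lineages(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
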