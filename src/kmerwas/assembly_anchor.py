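"""Ordering de novo scaffolds along a reference by longest alignment hit.

Real use consumes minimap2 PAF; :func:`internal_align` is an exact-match
seed-and-extend substitute so synthetic/desk-scale runs need no external
aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .kmer_engine import revcomp


class AnchorError(ValueError):
    pass


@dataclass(frozen=True)
class PafRecord:
    """The 12 mandatory PAF columns (0-based half-open coordinates)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    n_match: int
    block_len: int
    mapq: int

    def to_line(self) -> str:
        return "\t".join(map(str, (
            self.qname, self.qlen, self.qstart, self.qend, self.strand,
            self.tname, self.tlen, self.tstart, self.tend,
            self.n_match, self.block_len, self.mapq)))


def parse_paf(source: str | Path | Iterable[str]) -> tuple[list[PafRecord], int]:
    """Parse PAF lines; malformed lines are skipped and counted."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)
    records, skipped = [], 0
    for line in lines:
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        try:
            if len(parts) < 12 or parts[4] not in "+-":
                raise ValueError
            records.append(PafRecord(
                parts[0], int(parts[1]), int(parts[2]), int(parts[3]), parts[4],
                parts[5], int(parts[6]), int(parts[7]), int(parts[8]),
                int(parts[9]), int(parts[10]), int(parts[11])))
        except ValueError:
            skipped += 1
    return records, skipped


@dataclass
class AnchoredAssembly:
    """Scaffolds placed at their longest hit's reference coordinate."""

    anchors: dict[str, tuple[str, int, int, str]]  # scaffold -> (chrom, tstart, block_len, strand)
    unanchored: list[str]
    x_order: list[str] = field(default_factory=list)  # scaffolds by (chrom, position)
    x_rank: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.x_order:
            self.x_order = sorted(
                self.anchors, key=lambda s: (self.anchors[s][0], self.anchors[s][1], s))
        self.x_rank = {s: i for i, s in enumerate(self.x_order)}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("scaffold\tchrom\tposition\thit_length\tstrand\n")
            for s in self.x_order:
                chrom, pos, length, strand = self.anchors[s]
                fh.write(f"{s}\t{chrom}\t{pos}\t{length}\t{strand}\n")
            for s in self.unanchored:
                fh.write(f"{s}\t.\t.\t.\t.\n")


def anchor(
    alignments: Sequence[PafRecord],
    all_scaffolds: Iterable[str] | None = None,
) -> AnchoredAssembly:
    """Assign each scaffold the target start of its longest hit.

    "Longest" = largest alignment block length (PAF column 11); ties are
    broken by (smaller target name, smaller target start).  Scaffolds
    named in ``all_scaffolds`` but absent from the alignments are listed
    as unanchored.  The result is independent of input record order.
    """
    best: dict[str, PafRecord] = {}
    for rec in alignments:
        cur = best.get(rec.qname)
        if cur is None or (
            (-rec.block_len, rec.tname, rec.tstart)
            < (-cur.block_len, cur.tname, cur.tstart)
        ):
            best[rec.qname] = rec
    anchors = {q: (r.tname, r.tstart, r.block_len, r.strand) for q, r in best.items()}
    unanchored = sorted(set(all_scaffolds or []) - set(anchors))
    return AnchoredAssembly(anchors, unanchored)


def internal_align(
    scaffolds: Mapping[str, str],
    reference: Mapping[str, str],
    seed_length: int = 31,
) -> list[PafRecord]:
    """Exact-match seed-and-extend aligner emitting PAF-like records.

    Reports every maximal exact match of length >= seed_length on either
    strand; intended only for synthetic desk-scale inputs (real runs use
    an external aligner's PAF).
    """
    for tname, tseq in reference.items():
        if len(tseq) < seed_length:
            raise AnchorError(f"reference {tname} shorter than seed_length")
    index: dict[str, list[tuple[str, int]]] = {}
    for tname, tseq in reference.items():
        for i in range(len(tseq) - seed_length + 1):
            index.setdefault(tseq[i:i + seed_length], []).append((tname, i))
    records: list[PafRecord] = []
    for qname, qseq in scaffolds.items():
        qlen = len(qseq)
        for strand, seq in (("+", qseq), ("-", revcomp(qseq))):
            # per (target, diagonal) furthest-extended end, to dedupe seeds
            seen: dict[tuple[str, int], int] = {}
            for i in range(len(seq) - seed_length + 1):
                for tname, t in index.get(seq[i:i + seed_length], []):
                    diag = t - i
                    if seen.get((tname, diag), -1) >= i:
                        continue
                    tseq = reference[tname]
                    qs, ts = i, t
                    while qs > 0 and ts > 0 and seq[qs - 1] == tseq[ts - 1]:
                        qs -= 1
                        ts -= 1
                    qe, te = i + seed_length, t + seed_length
                    while qe < len(seq) and te < len(tseq) and seq[qe] == tseq[te]:
                        qe += 1
                        te += 1
                    seen[(tname, diag)] = qe
                    length = qe - qs
                    if strand == "+":
                        q0, q1 = qs, qe
                    else:
                        q0, q1 = qlen - qe, qlen - qs
                    records.append(PafRecord(
                        qname, qlen, q0, q1, strand, tname, len(tseq),
                        ts, te, length, length, 60))
    return records
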