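"""Lineage-specific k-mer painting of a target (hexaploid-like) genome.

Non-overlapping 100-kb segments of each target chromosome are assigned
to the donor lineage whose lineage-specific k-mers dominate the segment,
provided enough of the segment's k-mers are usable (single-locus in the
target subgenome, optionally seen in a landrace read panel) and present
in the diploid panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kmer_engine import KmerMatrix, KmerSet, canonical_windows

UNASSIGNED = "unassigned"
UNRESOLVED = "tauschii-unresolved"


class PaintError(ValueError):
    pass


@dataclass
class LineageKmerSets:
    """Per-lineage specificity partition of the panel k-mer space."""

    k: int
    specific: dict[str, np.ndarray]  # lineage -> sorted S{k} array, private to that lineage
    shared: np.ndarray  # present in >= 2 lineages


@dataclass
class SegmentAssignment:
    chrom: str
    start: int  # 1-based
    end: int  # inclusive
    n_windows: int  # k-mer windows starting in the segment
    n_usable_present: int
    specific_counts: dict[str, int]
    label: str
    partial: bool = False


def usable_kmers(
    assembly: Mapping[str, str],
    subgenome_chroms: Sequence[str],
    k: int = 51,
    landrace_sets: Sequence[KmerSet] | None = None,
) -> np.ndarray:
    """Canonical k-mers occurring at exactly one locus across the
    designated subgenome chromosomes, optionally intersected with the
    union of landrace k-mer sets.  Returns a sorted S{k} array."""
    chroms = [c for c in subgenome_chroms if c in assembly]
    if not chroms:
        raise PaintError("no subgenome chromosomes found in assembly")
    parts = []
    for c in chroms:
        canon, valid, _ = canonical_windows(assembly[c], k)
        parts.append(canon[valid])
    allk = np.concatenate(parts)
    uniq, counts = np.unique(allk, return_counts=True)
    usable = uniq[counts == 1]
    if landrace_sets is not None:
        union = np.unique(np.concatenate([s.kmers for s in landrace_sets]))
        usable = usable[np.isin(usable, union, assume_unique=True)]
    return usable


def lineage_specific(matrix: KmerMatrix, labels: Mapping[str, str]) -> LineageKmerSets:
    """Partition matrix rows by lineage specificity: a k-mer is
    Lx-specific iff present in >= 1 accession of Lx and none of the other
    lineages; all other rows are shared."""
    missing = [a for a in matrix.accessions if a not in labels]
    if missing:
        raise PaintError(f"unlabeled accessions: {missing}")
    lineages = sorted(set(labels[a] for a in matrix.accessions))
    pres = {}
    for lin in lineages:
        cols = [i for i, a in enumerate(matrix.accessions) if labels[a] == lin]
        pres[lin] = matrix.presence[:, cols].any(axis=1)
    n_lineages = np.sum([pres[lin] for lin in lineages], axis=0)
    specific = {lin: matrix.kmers[pres[lin] & (n_lineages == 1)] for lin in lineages}
    shared = matrix.kmers[n_lineages >= 2]
    return LineageKmerSets(matrix.k, specific, shared)


def _member_mask(sorted_set: np.ndarray, queries: np.ndarray) -> np.ndarray:
    if len(sorted_set) == 0:
        return np.zeros(len(queries), dtype=bool)
    idx = np.searchsorted(sorted_set, queries)
    idx[idx == len(sorted_set)] = 0
    return sorted_set[idx] == queries


def assign_segments(
    chrom: str,
    sequence: str,
    usable: np.ndarray,
    lineage_sets: LineageKmerSets,
    panel_kmers: np.ndarray,
    segment: int = 100_000,
    usable_floor: float = 0.20,
    margin_fraction: float = 0.0001,
    k: int | None = None,
) -> list[SegmentAssignment]:
    """Label each non-overlapping segment of ``sequence``.

    A k-mer belongs to the segment its forward-strand window starts in.
    With the nominal per-segment window count equal to the segment length
    (100,000 for 100-kb segments):

    * fewer than ``usable_floor`` x nominal k-mers both usable and present
      in the panel -> ``unassigned``;
    * otherwise the lineage whose specific count exceeds every other
      lineage's by >= ``margin_fraction`` x nominal (10 by default) wins;
    * no lineage clears the margin -> ``tauschii-unresolved``.

    Trailing partial segments use thresholds scaled by their actual
    window count and are flagged ``partial``.
    """
    k = k or lineage_sets.k
    if segment < k:
        raise PaintError("segment must be >= k")
    canon, valid, _ = canonical_windows(sequence, k)
    usable_mask = _member_mask(usable, canon) & valid
    present_mask = _member_mask(panel_kmers, canon) & valid
    up_mask = usable_mask & present_mask
    spec_masks = {
        lin: _member_mask(arr, canon) & up_mask
        for lin, arr in lineage_sets.specific.items()
    }
    lineages = sorted(spec_masks)
    out: list[SegmentAssignment] = []
    L = len(sequence)
    for s0 in range(0, L, segment):
        s1 = min(s0 + segment, L)
        n_windows = max(0, min(s1, len(canon)) - s0)
        partial = (s1 - s0) < segment
        nominal = segment if not partial else max(1, n_windows)
        sl = slice(s0, s0 + n_windows)
        n_up = int(up_mask[sl].sum())
        counts = {lin: int(m[sl].sum()) for lin, m in spec_masks.items()}
        if n_up < usable_floor * nominal:
            label = UNASSIGNED
        else:
            margin = margin_fraction * nominal
            ranked = sorted(lineages, key=lambda lin: -counts[lin])
            top = ranked[0]
            runner = counts[ranked[1]] if len(ranked) > 1 else 0
            label = top if counts[top] - runner >= margin else UNRESOLVED
        out.append(SegmentAssignment(chrom, s0 + 1, s1, n_windows, n_up,
                                     counts, label, partial))
    return out


def summarize_contribution(
    assignments: Sequence[SegmentAssignment],
) -> pd.DataFrame:
    """Percent of lineage-assigned segments per lineage, per chromosome
    and genome-wide ('all').  Chromosomes with zero assigned segments get
    NaN percentages."""
    lineages = sorted({lin for a in assignments for lin in a.specific_counts})
    rows = []
    chroms = list(dict.fromkeys(a.chrom for a in assignments))
    for scope in chroms + ["all"]:
        segs = [a for a in assignments if scope == "all" or a.chrom == scope]
        assigned = [a for a in segs if a.label in lineages]
        row: dict[str, object] = {"chrom": scope, "n_segments": len(segs),
                                  "n_assigned": len(assigned)}
        for lin in lineages:
            if assigned:
                row[f"pct_{lin}"] = 100.0 * sum(
                    1 for a in assigned if a.label == lin) / len(assigned)
            else:
                row[f"pct_{lin}"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def assignments_to_bed(
    assignments: Sequence[SegmentAssignment], path: str | Path
) -> None:
    """BED (0-based half-open) with label and counts in extra columns."""
    with open(path, "w") as fh:
        for a in assignments:
            counts = ",".join(f"{lin}={n}" for lin, n in sorted(a.specific_counts.items()))
            fh.write(f"{a.chrom}\t{a.start - 1}\t{a.end}\t{a.label}\t"
                     f"{a.n_usable_present}\t{counts}\n")
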