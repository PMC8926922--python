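"""Redundancy and residual-heterogeneity QC on the genotype matrix.

Pairwise identity-by-state (IBS) on a windowed SNP subsample flags
near-duplicate accessions (> 99.5% identity by default); the heterozygous
fraction of biallelic calls flags accessions with residual heterogeneity
(> 0.1 by default).  One representative per redundancy component is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import HET, MISSING, GenotypeMatrix

IBS_THRESHOLD = 99.5  # percent identity above which a pair is redundant
HET_THRESHOLD = 0.1  # het fraction above which an accession is flagged


@dataclass
class QcReport:
    ibs: pd.DataFrame  # columns: a, b, identity (percent, NaN if undefined)
    redundant_pairs: list[tuple[str, str]]
    het_fractions: dict[str, float]  # NaN when no non-missing calls
    flagged: list[str]
    missing_counts: dict[str, int]
    ibs_threshold: float = IBS_THRESHOLD
    het_threshold: float = HET_THRESHOLD


def sample_snps(
    matrix: GenotypeMatrix,
    window: int = 4_000_000,
    per_window: int = 100,
    seed: int | None = None,
) -> np.ndarray:
    """Sample up to ``per_window`` site indices uniformly without
    replacement from each non-overlapping window per chromosome; windows
    holding fewer sites contribute all of them.  Returns sorted indices."""
    if window <= 0:
        raise ValueError("window must be > 0")
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    win_id = (matrix.pos - 1) // window
    for chrom in dict.fromkeys(matrix.chrom.tolist()):
        on_chrom = np.flatnonzero(matrix.chrom == chrom)
        for w in np.unique(win_id[on_chrom]):
            idx = on_chrom[win_id[on_chrom] == w]
            if len(idx) > per_window:
                idx = rng.choice(idx, size=per_window, replace=False)
            chosen.append(idx)
    if not chosen:
        return np.empty(0, dtype=np.int64)
    return np.sort(np.concatenate(chosen))


def pairwise_ibs(calls: np.ndarray, accessions: Sequence[str]) -> pd.DataFrame:
    """Percent identical non-missing calls for every unordered pair, over
    sites non-missing in both members.  Het is a state of its own.
    Emits n(n-1)/2 rows; identity is NaN for pairs with no co-called site."""
    n = len(accessions)
    if n < 2:
        raise ValueError("pairwise_ibs requires >= 2 accessions")
    ok = calls != MISSING
    rows = []
    for i in range(n - 1):
        a = calls[:, i]
        both = ok[:, i][:, None] & ok[:, i + 1:]
        same = (a[:, None] == calls[:, i + 1:]) & both
        denom = both.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * same.sum(axis=0) / denom
        pct[denom == 0] = np.nan
        for off, p in enumerate(pct):
            rows.append((accessions[i], accessions[i + 1 + off], p))
    return pd.DataFrame(rows, columns=["a", "b", "identity"])


def het_fraction(matrix: GenotypeMatrix, accession: str) -> float:
    """Heterozygous calls over non-missing biallelic calls; NaN if none."""
    col = matrix.column(accession)
    ok = col != MISSING
    if not ok.any():
        return float("nan")
    return float((col[ok] == HET).sum() / ok.sum())


def qc_report(
    matrix: GenotypeMatrix,
    window: int = 4_000_000,
    per_window: int = 100,
    ibs_threshold: float = IBS_THRESHOLD,
    het_threshold: float = HET_THRESHOLD,
    seed: int | None = None,
) -> QcReport:
    idx = sample_snps(matrix, window, per_window, seed=seed)
    sub = matrix.calls[idx] if len(idx) else matrix.calls[:0]
    ibs = pairwise_ibs(sub, matrix.accessions)
    redundant = [
        (r.a, r.b) for r in ibs.itertuples()
        if np.isfinite(r.identity) and r.identity > ibs_threshold
    ]
    hets = {a: het_fraction(matrix, a) for a in matrix.accessions}
    flagged = [a for a, h in hets.items() if np.isfinite(h) and h > het_threshold]
    missing = {
        a: int((matrix.column(a) == MISSING).sum()) for a in matrix.accessions
    }
    return QcReport(ibs, redundant, hets, flagged, missing,
                    ibs_threshold, het_threshold)


def select_nonredundant(report: QcReport, accessions: Sequence[str]) -> list[str]:
    """Retain one accession per redundancy component (fewest missing
    calls, ties by lexicographic id) and drop heterogeneity-flagged
    accessions.  Returned in the input panel order."""
    g = nx.Graph()
    g.add_nodes_from(accessions)
    g.add_edges_from(report.redundant_pairs)
    flagged = set(report.flagged)
    keep: set[str] = set()
    for comp in nx.connected_components(g):
        candidates = sorted(comp - flagged,
                            key=lambda a: (report.missing_counts.get(a, 0), a))
        if candidates:
            keep.add(candidates[0])
    return [a for a in accessions if a in keep]
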