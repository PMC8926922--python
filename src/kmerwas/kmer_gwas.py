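"""Correlation-prefiltered k-mer association mapping.

Candidate k-mers are those whose presence/absence correlates with the
phenotype (|Pearson r| above a threshold, 0.2 by default).  Each
candidate is scored by a likelihood-ratio test between nested Gaussian
linear models (phenotype ~ intercept + PCs, with and without the
presence term); the statistic is n*ln(RSS_null/RSS_full) on 1 df.  The
genome-wide significance cutoff uses a Bonferroni correction on the
effective number of variants, i.e. total tested k-mers divided by k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kmer_engine import (
    KmerMatrix,
    canonical_windows,
    canonicalize,
    pack_kmer_array,
    packed_to_string,
    packed_width,
    string_to_packed,
)

SCORE_CAP = 300.0  # -log10 p reported for p < 1e-300 (perfect fits)


class GwasError(ValueError):
    pass


@dataclass
class ThresholdSpec:
    """Effective-variant Bonferroni threshold."""

    alpha: float
    n_tested: int
    k: int

    @property
    def effective_tests(self) -> float:
        return max(1.0, self.n_tested / self.k)

    @property
    def score_threshold(self) -> float:
        return -math.log10(self.alpha / self.effective_tests)

    @property
    def score_threshold_rounded(self) -> float:
        return round(self.score_threshold, 1)


def bonferroni_threshold(n_tested: int, k: int = 51, alpha: float = 0.05) -> ThresholdSpec:
    """-log10(alpha / (n_tested / k)): the association-score cutoff after
    correcting for the effective number of variants (each SNP or SV
    produces up to k overlapping k-mer variants, hence the division)."""
    if n_tested < 1:
        raise GwasError("n_tested must be >= 1")
    return ThresholdSpec(alpha=alpha, n_tested=n_tested, k=k)


@dataclass
class AssociationRecord:
    kmer: str
    pearson_r: float
    score: float  # -log10 LRT p
    direction: int  # sign of the presence coefficient in the full model
    degenerate: bool = False  # presence collinear with covariates
    placements: list[tuple[str, int, str]] = field(default_factory=list)  # (target, 1-based pos, strand)


def align_phenotype(
    matrix: KmerMatrix, phenotype: Mapping[str, float] | pd.Series
) -> tuple[KmerMatrix, np.ndarray]:
    """Drop accessions without a (finite) phenotype from both sides."""
    pheno = pd.Series(phenotype).astype(float)
    ids = [a for a in matrix.accessions if a in pheno.index and np.isfinite(pheno[a])]
    if len(ids) < 4:
        raise GwasError("phenotype covers < 4 matrix accessions")
    return matrix.subset_accessions(ids), pheno[ids].to_numpy()


def prefilter(
    matrix: KmerMatrix,
    phenotype: Mapping[str, float] | pd.Series,
    threshold: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pearson correlation between every row and the phenotype.

    Returns (row indices with |r| > threshold, their r values, number of
    zero-variance rows skipped).  Accessions lacking a phenotype are
    dropped pairwise before correlating.
    """
    sub, y = align_phenotype(matrix, phenotype)
    if np.std(y) == 0:
        raise GwasError("zero-variance phenotype")
    x = sub.presence
    n = x.shape[1]
    row_sum = x.sum(axis=1).astype(float)
    mean_x = row_sum / n
    var_x = mean_x * (1 - mean_x)  # Bernoulli row variance (biased form)
    yc = (y - y.mean()).astype(np.float32)
    # chunked float32 matmul avoids one full float64 copy of the matrix
    cov = np.empty(len(row_sum))
    step = 1 << 18
    for i in range(0, x.shape[0], step):
        cov[i:i + step] = x[i:i + step] @ yc
    cov /= n
    sd_y = math.sqrt(float(yc.astype(float) @ yc.astype(float)) / n)
    nz = var_x > 0
    r = np.zeros(len(row_sum))
    r[nz] = cov[nz] / (np.sqrt(var_x[nz]) * sd_y)
    keep = nz & (np.abs(r) > threshold)
    return np.flatnonzero(keep), r[keep], int((~nz).sum())


def _null_basis(n: int, covariates: np.ndarray | None) -> np.ndarray:
    """Orthonormal basis of the null design (intercept + covariates)."""
    c = np.empty((n, 0)) if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    if c.shape[0] != n:
        c = c.T
    if n < c.shape[1] + 3:
        raise GwasError("too few observations for the model")
    design = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise GwasError("covariate matrix not full rank with intercept")
    q, _ = np.linalg.qr(design)
    return q


def lrt_scores_bulk(
    presence_rows: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nested-model likelihood-ratio tests for many presence vectors.

    Null: y ~ 1 + covariates.  Full: null + presence.  With the Gaussian
    variance profiled out the statistic is n*ln(RSS_null/RSS_full),
    chi-square on 1 df.  Implemented by projecting out the null design:
    RSS_full = RSS_null - (e_x . e_y)^2 / ||e_x||^2 where e_* are
    residuals against the null basis.  Returns arrays
    (score = -log10 p, direction, degenerate).
    """
    y = np.asarray(phenotype, dtype=float)
    x = np.atleast_2d(np.asarray(presence_rows, dtype=float))
    n = len(y)
    q = _null_basis(n, covariates)
    e_y = y - q @ (q.T @ y)
    rss0 = float(e_y @ e_y)
    xq = x @ q
    ssx = (x**2).sum(axis=1)
    den = ssx - (xq**2).sum(axis=1)  # ||e_x||^2
    num = x @ e_y  # e_x . e_y  (e_y is orthogonal to the null space)
    degenerate = den <= 1e-9 * np.maximum(ssx, 1.0)
    safe_den = np.where(degenerate, 1.0, den)
    beta = num / safe_den
    rss1 = np.maximum(rss0 - num**2 / safe_den, 0.0)
    direction = np.where(beta >= 0, 1, -1)
    perfect = rss1 <= 1e-12 * max(rss0, 1.0)
    with np.errstate(divide="ignore"):
        stat = n * np.log(rss0 / np.where(perfect, 1.0, rss1))
    stat = np.maximum(stat, 0.0)
    score = np.where(stat > 0, -stats.chi2.logsf(stat, df=1) / math.log(10), 0.0)
    score = np.where(perfect, SCORE_CAP, np.minimum(score, SCORE_CAP))
    score = np.where(degenerate, 0.0, score)
    direction = np.where(degenerate, 1, direction)
    return score, direction, degenerate


def lrt_score(
    presence: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, int, bool]:
    """Single-vector wrapper around :func:`lrt_scores_bulk`."""
    score, direction, degenerate = lrt_scores_bulk(
        np.asarray(presence, dtype=float)[None, :], phenotype, covariates)
    return float(score[0]), int(direction[0]), bool(degenerate[0])


def score_candidates(
    matrix: KmerMatrix,
    phenotype: Mapping[str, float] | pd.Series,
    covariates: np.ndarray | None = None,
    prefilter_threshold: float = 0.2,
) -> list[AssociationRecord]:
    """Prefilter + LRT over all candidate rows of the matrix.

    ``covariates`` must be aligned to the phenotype-covered accession
    subset (see :func:`run_gwas` for the full pipeline that recomputes
    PCA on that subset).
    """
    sub, y = align_phenotype(matrix, phenotype)
    idx, rvals, _ = prefilter(matrix, phenotype, prefilter_threshold)
    if len(idx) == 0:
        return []
    scores, directions, degenerate = lrt_scores_bulk(
        sub.presence[idx], y, covariates)
    return [
        AssociationRecord(
            kmer=packed_to_string(sub.kmers[row], sub.k), pearson_r=float(r),
            score=float(sc), direction=int(d), degenerate=bool(dg))
        for row, r, sc, d, dg in zip(idx, rvals, scores, directions, degenerate)
    ]


def run_gwas(
    matrix: KmerMatrix,
    phenotype: Mapping[str, float] | pd.Series,
    n_pcs: int = 3,
    prefilter_threshold: float = 0.2,
    alpha: float = 0.05,
    pca_rows: int = 100_000,
    pca_seed: int = 0,
) -> tuple[list[AssociationRecord], ThresholdSpec]:
    """Full association scan: PCA covariates (recomputed on the
    phenotype-covered accessions), prefilter, LRT scores, and the
    effective-variant Bonferroni threshold for n_tested = all matrix rows."""
    from .kmer_engine import sample_rows
    from .pop_structure import pca

    sub, y = align_phenotype(matrix, phenotype)
    covariates = None
    if n_pcs > 0:
        pcs_src = sub
        if sub.n_rows > pca_rows:
            pcs_src = sample_rows(sub, pca_rows, seed=pca_seed)
        covariates, _ = pca(pcs_src, dims=n_pcs)
    records = score_candidates(matrix, phenotype, covariates, prefilter_threshold)
    spec = bonferroni_threshold(matrix.n_rows, matrix.k, alpha)
    return records, spec


# --- placement ----------------------------------------------------------


def place_kmers(
    records: Sequence[AssociationRecord],
    targets: Mapping[str, str],
) -> tuple[list[AssociationRecord], int]:
    """Locate every exact occurrence (either strand) of each record's
    k-mer in the target sequences.

    A placement is (target id, 1-based start of the forward-strand
    window, strand).  Returns (records, number left unplaced).
    """
    if not records:
        return [], 0
    k = len(records[0].kmer)
    kw = packed_width(k)
    want = np.array([string_to_packed(canonicalize(r.kmer)) for r in records],
                    dtype=f"S{kw}")
    order = np.argsort(want)
    sorted_want = want[order]
    hits: dict[int, list[tuple[str, int, str]]] = {i: [] for i in range(len(records))}
    for tname, seq in targets.items():
        canon, valid, fwd = canonical_windows(seq, k)
        pos = np.searchsorted(sorted_want, canon)
        pos[pos == len(sorted_want)] = 0
        match = valid & (sorted_want[pos] == canon)
        for w in np.flatnonzero(match):
            ridx = int(order[pos[w]])
            strand = "+" if fwd[w] == want[ridx] else "-"
            # canonical query: forward window equal to the canonical form
            # means the k-mer occurs on the forward strand
            hits[ridx].append((tname, int(w) + 1, strand))
    unplaced = 0
    for i, rec in enumerate(records):
        rec.placements = hits[i]
        if not hits[i]:
            unplaced += 1
    return list(records), unplaced


# --- plot table ---------------------------------------------------------


@dataclass
class PlotTable:
    rows: pd.DataFrame  # x, score, count, direction
    mode: str  # "reference" | "anchored"
    block: int
    threshold: float | None  # significance cutoff carried as metadata
    n_excluded: int  # records dropped (unplaced)
    axis_legend: dict[int, str]  # x index -> block/scaffold description


def plot_table(
    records: Sequence[AssociationRecord],
    mode: str = "reference",
    block: int = 10_000,
    report_floor: float = 6.0,
    anchored=None,
    threshold: float | None = None,
    target_lengths: Mapping[str, int] | None = None,
) -> PlotTable:
    """Aggregate placed records with score > report_floor into plot dots.

    Reference mode: each integer x corresponds to the ``block``-sized
    genomic block starting at position x*block (1-based positions p map
    to x = p // block), with per-chromosome offsets so x is unique
    genome-wide.  Anchored mode: x = rank of the placement's scaffold in
    the anchored assembly order.  Dots are keyed by (x, score rounded to
    1 decimal, direction); count is the number of k-mer placements there.
    """
    if mode not in ("reference", "anchored"):
        raise GwasError(f"unknown mode {mode!r}")
    if mode == "anchored" and anchored is None:
        raise GwasError("anchored mode requires an AnchoredAssembly")
    dots: list[tuple[str, int, float, int]] = []  # target, local x, score, direction
    n_excluded = 0
    for rec in records:
        if rec.score <= report_floor:
            continue
        if not rec.placements:
            n_excluded += 1
            continue
        for target, pos, _strand in rec.placements:
            if mode == "reference":
                dots.append((target, pos // block, round(rec.score, 1), rec.direction))
            elif target in anchored.x_rank:
                dots.append((target, 0, round(rec.score, 1), rec.direction))
            else:
                n_excluded += 1
    if mode == "reference":
        targets = sorted({d[0] for d in dots})
        if target_lengths is not None:
            targets = sorted(target_lengths)
        offsets: dict[str, int] = {}
        off = 0
        for t in targets:
            offsets[t] = off
            if target_lengths is not None:
                off += target_lengths[t] // block + 1
            else:
                off += max((d[1] for d in dots if d[0] == t), default=0) + 1
        xs = [(offsets[t] + bx, sc, d) for t, bx, sc, d in dots]
        legend = {offsets[t] + bx: f"{t}:{bx * block}-{(bx + 1) * block - 1}"
                  for t, bx, sc, d in dots}
    else:
        xs = [(anchored.x_rank[t], sc, d) for t, _bx, sc, d in dots]
        legend = {anchored.x_rank[t]: t for t, _bx, _sc, _d in dots}
    agg: dict[tuple[int, float, int], int] = {}
    for key in xs:
        agg[key] = agg.get(key, 0) + 1
    rows = pd.DataFrame(
        [(x, s_, c, d) for (x, s_, d), c in sorted(agg.items())],
        columns=["x", "score", "count", "direction"],
    )
    return PlotTable(rows, mode, block, threshold, n_excluded, legend)


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        if r.placements:
            for t, p, s in r.placements:
                rows.append((r.kmer, r.pearson_r, r.score, r.direction, t, p, s))
        else:
            rows.append((r.kmer, r.pearson_r, r.score, r.direction, None, None, None))
    return pd.DataFrame(
        rows, columns=["kmer", "pearson_r", "score", "direction",
                       "target", "position", "strand"])
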