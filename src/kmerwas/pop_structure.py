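"""Population structure and diversity statistics.

UPGMA phylogeny (with bootstrap supports) and PCA are computed from the
k-mer presence/absence matrix; F_ST (Weir & Cockerham 1984 variance
components, windowed as a ratio of sums) and LD decay (composite r² from
allele dosages) are computed from the genotype matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, HET, HOM_ALT, MISSING
from .kmer_engine import KmerMatrix


class PopStructureError(ValueError):
    pass


# --- distances and trees ------------------------------------------------


def kmer_distance(matrix: KmerMatrix) -> tuple[np.ndarray, list[str]]:
    """Hamming-proportion distance between accession presence columns."""
    if matrix.n_accessions < 2:
        raise PopStructureError("need >= 2 accessions")
    if matrix.n_rows == 0:
        raise PopStructureError("empty k-mer matrix")
    x = matrix.presence.astype(np.uint32)
    # pairwise mismatches via dot products on 0/1 columns
    ones = x.T @ x
    zeros = (1 - x).T @ (1 - x)
    d = 1.0 - (ones + zeros) / matrix.n_rows
    np.fill_diagonal(d, 0.0)
    return d, list(matrix.accessions)


def jaccard_distance(matrix: KmerMatrix) -> tuple[np.ndarray, list[str]]:
    """1 - |intersection| / |union| of presence columns (alternative metric)."""
    x = matrix.presence.astype(np.uint32)
    inter = x.T @ x
    totals = x.sum(axis=0)
    union = totals[:, None] + totals[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return d, list(matrix.accessions)


@dataclass
class TreeNode:
    """Rooted ultrametric tree node (UPGMA output)."""

    name: str | None = None  # leaf label
    children: list["TreeNode"] = field(default_factory=list)
    height: float = 0.0  # distance from this node down to any leaf
    support: int | None = None  # bootstrap percent for internal nodes

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes (including the root)."""
        out = []
        if not self.is_leaf:
            out.append(frozenset(self.leaves()))
            for c in self.children:
                out.extend(c.clades())
        return out

    def internal_nodes(self) -> list["TreeNode"]:
        out = []
        if not self.is_leaf:
            out.append(self)
            for c in self.children:
                out.extend(c.internal_nodes())
        return out

    def to_newick(self) -> str:
        return self._newick(None) + ";"

    def _newick(self, parent_height: float | None) -> str:
        bl = "" if parent_height is None else f":{parent_height - self.height:.6g}"
        if self.is_leaf:
            return f"{self.name}{bl}"
        inner = ",".join(c._newick(self.height) for c in self.children)
        label = "" if self.support is None else str(self.support)
        return f"({inner}){label}{bl}"


def upgma(dist: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """UPGMA agglomeration: merge the closest cluster pair, node height =
    half the merge distance, linkage = size-weighted arithmetic mean.
    Ties are broken by the lexicographically smallest (min-leaf) pair."""
    d = np.asarray(dist, dtype=float)
    if np.isnan(d).any():
        raise PopStructureError("distance matrix contains NaN")
    if d.shape[0] != d.shape[1] or d.shape[0] != len(labels):
        raise PopStructureError("distance matrix / label shape mismatch")
    nodes = {i: TreeNode(name=labels[i]) for i in range(len(labels))}
    sizes = {i: 1 for i in range(len(labels))}
    minleaf = {i: labels[i] for i in range(len(labels))}
    d = d.copy()
    active = set(range(len(labels)))
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                key = (d[i, j],) + tuple(sorted((minleaf[i], minleaf[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        h = d[i, j] / 2.0
        merged = TreeNode(children=[nodes[i], nodes[j]], height=h)
        for m in active - {i, j}:
            d[i, m] = d[m, i] = (
                sizes[i] * d[i, m] + sizes[j] * d[j, m]
            ) / (sizes[i] + sizes[j])
        nodes[i] = merged
        sizes[i] += sizes[j]
        minleaf[i] = min(minleaf[i], minleaf[j])
        active.remove(j)
    return nodes[active.pop()]


def bootstrap_tree(
    matrix: KmerMatrix,
    replicates: int = 100,
    seed: int | None = None,
    metric=kmer_distance,
) -> TreeNode:
    """UPGMA tree with bootstrap supports: matrix rows are resampled with
    replacement per replicate and support is the percent of replicate
    trees containing each original clade."""
    if matrix.n_accessions < 3:
        raise PopStructureError("need >= 3 accessions for bootstrapping")
    if replicates < 1:
        raise PopStructureError("replicates must be >= 1")
    d, labels = metric(matrix)
    tree = upgma(d, labels)
    counts: dict[frozenset[str], int] = {c: 0 for c in tree.clades()}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        idx = rng.integers(0, matrix.n_rows, size=matrix.n_rows)
        rep = KmerMatrix(matrix.k, matrix.kmers[idx], list(matrix.accessions),
                         matrix.presence[idx])
        rd, _ = metric(rep)
        rep_clades = set(upgma(rd, labels).clades())
        for c in counts:
            if c in rep_clades:
                counts[c] += 1
    for node in tree.internal_nodes():
        node.support = round(100 * counts[frozenset(node.leaves())] / replicates)
    return tree


# --- PCA ----------------------------------------------------------------


def pca(matrix: KmerMatrix, dims: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """PCA of accessions in k-mer presence space.

    Returns (scores, explained_variance_ratio); scores has one row per
    accession.  Sign convention: the largest-magnitude k-mer loading of
    each component is positive.
    """
    if matrix.n_rows < dims or matrix.n_accessions < dims + 1:
        raise PopStructureError("matrix too small for requested dims")
    x = matrix.presence.T.astype(float)  # accessions x kmers
    x -= x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if s[0] == 0:
        raise PopStructureError("zero-variance matrix")
    for c in range(dims):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            vt[c] = -vt[c]
            u[:, c] = -u[:, c]
    scores = u[:, :dims] * s[:dims]
    evr = (s**2) / (s**2).sum()
    return scores, evr[:dims]


# --- Venn partition -----------------------------------------------------

VENN_CELLS = ("L1", "L2", "L3", "L1&L2", "L1&L3", "L2&L3", "L1&L2&L3")


def venn_partition(
    matrix: KmerMatrix, labels: Mapping[str, str]
) -> tuple[dict[str, int], dict[str, float]]:
    """Assign every matrix row to its cell of the 3-set Venn diagram of
    lineage presence (present in >= 1 accession of a lineage).  Returns
    (counts, percentages over all rows)."""
    missing = [a for a in matrix.accessions if a not in labels]
    if missing:
        raise PopStructureError(f"unlabeled accessions: {missing}")
    lineages = ("L1", "L2", "L3")
    masks = []
    for lin in lineages:
        cols = [i for i, a in enumerate(matrix.accessions) if labels[a] == lin]
        masks.append(matrix.presence[:, cols].any(axis=1) if cols
                     else np.zeros(matrix.n_rows, dtype=bool))
    code = masks[0].astype(int) + 2 * masks[1] + 4 * masks[2]
    cell_of = {1: "L1", 2: "L2", 4: "L3", 3: "L1&L2", 5: "L1&L3",
               6: "L2&L3", 7: "L1&L2&L3"}
    counts = {name: 0 for name in VENN_CELLS}
    vals, cnts = np.unique(code, return_counts=True)
    for v, c in zip(vals.tolist(), cnts.tolist()):
        if v in cell_of:
            counts[cell_of[v]] = c
    total = max(1, matrix.n_rows)
    pct = {name: 100.0 * c / total for name, c in counts.items()}
    return counts, pct


# --- F_ST ---------------------------------------------------------------


def wc_fst_components(
    calls: np.ndarray, pop_cols: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) variance components for diploid
    genotypes.  Returns (a, a+b+c) arrays; sites with < 2 populations
    having >= 1 called individual get NaN."""
    r = len(pop_cols)
    n_i, p_i, h_i = [], [], []
    for cols in pop_cols:
        c = calls[:, cols]
        called = c != MISSING
        n = called.sum(axis=1).astype(float)  # individuals called
        with np.errstate(invalid="ignore", divide="ignore"):
            p = ((c == HOM_ALT).sum(axis=1) + 0.5 * (c == HET).sum(axis=1)) / n
            h = (c == HET).sum(axis=1) / n
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.vstack(n_i)  # (r, sites)
    p_i = np.vstack(p_i)
    h_i = np.vstack(h_i)
    valid = (n_i > 0).sum(axis=0) == r
    nsum = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = nsum / r
        nc = (nsum - (n_i**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / nsum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / nsum
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    tot = a + b + c
    a = np.where(valid, a, np.nan)
    tot = np.where(valid, tot, np.nan)
    return a, tot


@dataclass
class FstWindow:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    fst: float  # ratio-of-sums ("weighted") estimator
    mean_fst: float  # mean of per-site ratios
    n_sites: int


def fst_windows(
    matrix: GenotypeMatrix,
    populations: Mapping[str, Sequence[str]],
    window: int = 1_000_000,
    step: int = 100_000,
) -> dict[tuple[str, str], list[FstWindow]]:
    """Sliding-window pairwise F_ST for every population pair.

    Windowed value = sum(a) / sum(a+b+c) over sites in the window (the
    weighted estimator); the per-site-mean variant is reported alongside.
    """
    if window <= 0:
        raise PopStructureError("window must be > 0")
    names = list(populations)
    if len(names) < 2:
        raise PopStructureError("need >= 2 populations")
    col_of = {a: i for i, a in enumerate(matrix.accessions)}
    cols = {}
    for name in names:
        members = [col_of[a] for a in populations[name]]
        if len(members) < 2:
            raise PopStructureError(f"population {name} has < 2 accessions")
        cols[name] = np.array(members)
    out: dict[tuple[str, str], list[FstWindow]] = {}
    for x in range(len(names)):
        for y in range(x + 1, len(names)):
            pair = (names[x], names[y])
            a, tot = wc_fst_components(matrix.calls, [cols[names[x]], cols[names[y]]])
            ok = np.isfinite(tot) & (tot != 0)
            out[pair] = _windowize(matrix, a, tot, ok, window, step)
    return out


def _windowize(matrix, a, tot, ok, window, step) -> list[FstWindow]:
    wins: list[FstWindow] = []
    for chrom in dict.fromkeys(matrix.chrom.tolist()):
        on = np.flatnonzero((matrix.chrom == chrom) & ok)
        if len(on) == 0:
            continue
        pos = matrix.pos[on]
        last = int(pos.max())
        start = 1
        while start <= last:
            end = start + window - 1
            inw = on[(pos >= start) & (pos <= end)]
            if len(inw):
                denom = tot[inw].sum()
                ratio = float(a[inw].sum() / denom) if denom != 0 else float("nan")
                with np.errstate(invalid="ignore", divide="ignore"):
                    persite = a[inw] / tot[inw]
                wins.append(FstWindow(chrom, start, end, ratio,
                                      float(np.nanmean(persite)), len(inw)))
            start += step
    return wins


def fst_global(matrix: GenotypeMatrix, populations: Mapping[str, Sequence[str]]) -> float:
    """Genome-wide ratio-of-sums Weir & Cockerham F_ST over the first
    population pair (convenience for two-population panels)."""
    col_of = {a: i for i, a in enumerate(matrix.accessions)}
    names = list(populations)[:2]
    pair_cols = [np.array([col_of[x] for x in populations[n]]) for n in names]
    a_arr, tot = wc_fst_components(matrix.calls, pair_cols)
    ok = np.isfinite(tot)
    den = float(np.nansum(tot[ok]))
    return float(np.nansum(a_arr[ok]) / den) if den else float("nan")


# --- LD decay -----------------------------------------------------------


@dataclass
class LdBin:
    region: str
    low: int  # distance bin lower edge, exclusive
    high: int  # inclusive
    mean_r2: float
    n_pairs: int


def ld_decay(
    matrix: GenotypeMatrix,
    max_dist: int = 5_000_000,
    bin_size: int = 10_000,
    regions: Sequence[tuple[str, int, int, str]] | None = None,
) -> tuple[list[LdBin], dict[str, float | None]]:
    """Composite-LD decay: r² between allele-dosage vectors of site pairs
    within ``max_dist``, binned by distance.

    ``regions`` optionally restricts pairs to labeled intervals
    (chrom, 1-based start, end, label); otherwise one "all" region is
    used.  Returns the bins and, per region, the lower edge of the first
    bin whose mean r² drops below 0.1 (None if it never does).
    """
    dose = matrix.dosage()
    # mean-impute missing dosages per site so r² stays a plain correlation
    means = np.nanmean(dose, axis=1, keepdims=True)
    nanmask = np.isnan(dose)
    if nanmask.any():
        dose[nanmask] = np.broadcast_to(means, dose.shape)[nanmask]
    if regions is None:
        regions = [(c, 1, int(matrix.pos[matrix.chrom == c].max()), "all")
                   for c in dict.fromkeys(matrix.chrom.tolist())]
    sums: dict[tuple[str, int], list[float]] = {}
    counts: dict[tuple[str, int], int] = {}
    for chrom, start, end, label in regions:
        sel = np.flatnonzero(
            (matrix.chrom == chrom) & (matrix.pos >= start) & (matrix.pos <= end)
        )
        if len(sel) < 2:
            continue
        sub = dose[sel]
        pos = matrix.pos[sel]
        sd = sub.std(axis=1)
        poly = sd > 0
        sub, pos, sd = sub[poly], pos[poly], sd[poly]
        if len(pos) < 2:
            continue
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        r = (z @ z.T) / sub.shape[1]
        r2 = r**2
        dmat = np.abs(pos[:, None] - pos[None, :])
        iu = np.triu_indices(len(pos), k=1)
        d = dmat[iu]
        v = r2[iu]
        inrange = (d > 0) & (d <= max_dist)
        d, v = d[inrange], v[inrange]
        b = ((d - 1) // bin_size).astype(int)
        for bi in np.unique(b):
            key = (label, int(bi))
            m = b == bi
            sums[key] = sums.get(key, 0.0) + float(v[m].sum())
            counts[key] = counts.get(key, 0) + int(m.sum())
    bins = [
        LdBin(label, bi * bin_size, (bi + 1) * bin_size,
              sums[(label, bi)] / counts[(label, bi)], counts[(label, bi)])
        for (label, bi) in sorted(sums)
    ]
    decay_at: dict[str, float | None] = {}
    for label in {b.region for b in bins}:
        decay_at[label] = None
        for b in sorted([x for x in bins if x.region == label], key=lambda x: x.low):
            if b.mean_r2 < 0.1:
                decay_at[label] = float(b.low)
                break
    return bins, decay_at


def ld_bins_to_frame(bins: list[LdBin]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.region, b.low, b.high, b.mean_r2, b.n_pairs) for b in bins],
        columns=["region", "dist_low", "dist_high", "mean_r2", "n_pairs"],
    )
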