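import numpy as np
import pytest

from kmerwas import kmer_engine as ke
from kmerwas import pop_structure as ps
from kmerwas import synthetic_data as sd
from kmerwas.genotypes import GenotypeMatrix
from .conftest import make_kmerset


def matrix_from_presence(presence, k=5):
    """KmerMatrix with arbitrary (distinct) k-mers and given presence."""
    presence = np.asarray(presence, dtype=bool)
    n_rows, n_acc = presence.shape
    rng = np.random.default_rng(123)
    kmers = set()
    while len(kmers) < n_rows:
        kmers.add(ke.canonicalize("".join(rng.choice(list("ACGT"), k))))
    packed = np.sort(np.array([ke.string_to_packed(s) for s in sorted(kmers)],
                              dtype=f"S{ke.packed_width(k)}"))
    return ke.KmerMatrix(k, packed, [f"a{i}" for i in range(n_acc)], presence)


def make_gm(pos, calls, chrom=None, accessions=None):
    calls = np.asarray(calls, dtype=np.int8)
    m, n = calls.shape
    chrom = chrom or ["c1"] * m
    return GenotypeMatrix(
        np.array(chrom, dtype=object), np.array(pos, dtype=np.int64),
        np.array(["A"] * m, dtype=object), np.array(["T"] * m, dtype=object),
        accessions or [f"a{i}" for i in range(n)], calls)


def wc_oracle_site(genos_by_pop):
    """Scalar Weir & Cockerham (1984) a, b, c for one site.

    ``genos_by_pop``: list of lists of diploid genotype codes (0/1/2).
    Independent loop-based route used to check the vectorized version.
    """
    r = len(genos_by_pop)
    n_i = [len(g) for g in genos_by_pop]
    p_i = [sum(g) / (2 * n) for g, n in zip(genos_by_pop, n_i)]
    h_i = [sum(1 for x in g if x == 1) / n for g, n in zip(genos_by_pop, n_i)]
    nsum = sum(n_i)
    nbar = nsum / r
    nc = (nsum - sum(n * n for n in n_i) / nsum) / (r - 1)
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / nsum
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(n_i, h_i)) / nsum
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestKmerDistance:
    def test_hand_count(self):
        presence = np.array([[1, 1], [0, 1], [1, 1], [1, 0]], dtype=bool)
        d, labels = ps.kmer_distance(matrix_from_presence(presence))
        assert d[0, 1] == pytest.approx(0.5)

    def test_identical_columns_zero(self):
        presence = np.array([[1, 1], [0, 0], [1, 1], [0, 0]], dtype=bool)
        d, _ = ps.kmer_distance(matrix_from_presence(presence))
        assert d[0, 1] == 0.0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        presence = rng.random((500, 8)) < 0.5
        d, _ = ps.kmer_distance(matrix_from_presence(presence))
        for i in range(8):
            for j in range(8):
                expected = np.mean(presence[:, i] != presence[:, j])
                assert d[i, j] == pytest.approx(expected)

    def test_jaccard_identical_columns_zero(self):
        presence = np.array([[1, 1], [1, 1], [0, 0], [1, 0]], dtype=bool)
        d, _ = ps.jaccard_distance(matrix_from_presence(presence))
        assert d[0, 0] == 0.0
        assert d[0, 1] == pytest.approx(1 - 2 / 3)


class TestUpgma:
    def test_forced_merge_order(self):
        d = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        tree = ps.upgma(d, ["A", "B", "C"])
        assert tree.height == pytest.approx(2.0)
        inner = [c for c in tree.children if not c.is_leaf][0]
        assert sorted(inner.leaves()) == ["A", "B"]
        assert inner.height == pytest.approx(1.0)

    def test_degenerate_equal_distances_deterministic(self):
        d = np.full((4, 4), 3.0)
        np.fill_diagonal(d, 0.0)
        t1 = ps.upgma(d, ["d", "c", "b", "a"])
        t2 = ps.upgma(d, ["d", "c", "b", "a"])
        assert t1.to_newick() == t2.to_newick()
        # lexicographically smallest pair merged first
        pairs = [sorted(n.leaves()) for n in t1.internal_nodes()
                 if len(n.leaves()) == 2]
        assert ["a", "b"] in pairs

    def test_matches_scipy_average_linkage_heights(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(2)
        for _ in range(10):
            d = squareform(rng.random(15))  # 6 leaves
            tree = ps.upgma(d, list("ABCDEF"))
            heights = sorted(n.height for n in tree.internal_nodes())
            link = linkage(squareform(d), method="average")
            expected = sorted(link[:, 2] / 2)
            assert np.allclose(heights, expected)

    def test_ultrametric_invariant(self, small_matrix):
        d, labels = ps.kmer_distance(small_matrix)
        tree = ps.upgma(d, labels)

        def leaf_depths(node, acc):
            if node.is_leaf:
                return [acc]
            out = []
            for c in node.children:
                out.extend(leaf_depths(c, acc + (node.height - c.height)))
            return out

        depths = leaf_depths(tree, 0.0)
        assert np.allclose(depths, depths[0], atol=1e-9)

    def test_nan_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ps.PopStructureError):
            ps.upgma(d, ["a", "b"])


class TestBootstrap:
    def test_identical_column_clusters_full_support(self):
        block = np.zeros((60, 6), dtype=bool)
        block[:30, :3] = True
        block[30:, 3:] = True
        m = matrix_from_presence(block)
        tree = ps.bootstrap_tree(m, replicates=30, seed=1)
        for node in tree.internal_nodes():
            leaves = sorted(node.leaves())
            if leaves in (["a0", "a1", "a2"], ["a3", "a4", "a5"]):
                assert node.support == 100

    def test_supports_in_bounds(self, small_matrix):
        tree = ps.bootstrap_tree(small_matrix, replicates=20, seed=2)
        for node in tree.internal_nodes():
            assert 0 <= node.support <= 100

    def test_lineage_clades_strongly_supported(self, small_panel, small_matrix):
        tree = ps.bootstrap_tree(small_matrix, replicates=50, seed=3)
        lineages = {}
        for aid, lin in small_panel.truth.lineage_of.items():
            lineages.setdefault(lin, set()).add(aid)
        clades = {frozenset(n.leaves()): n.support for n in tree.internal_nodes()}
        for lin, members in lineages.items():
            assert clades.get(frozenset(members), 0) >= 95

    def test_replicates_floor(self, small_matrix):
        with pytest.raises(ps.PopStructureError):
            ps.bootstrap_tree(small_matrix, replicates=0)

    def test_newick_output_parses(self, small_matrix):
        from io import StringIO
        from Bio import Phylo
        tree = ps.bootstrap_tree(small_matrix, replicates=5, seed=4)
        parsed = Phylo.read(StringIO(tree.to_newick()), "newick")
        assert parsed.count_terminals() == small_matrix.n_accessions


class TestPca:
    def test_planted_groups_separate_on_pc1(self):
        rng = np.random.default_rng(5)
        presence = rng.random((400, 10)) < 0.5
        presence[:150, :5] = True
        presence[:150, 5:] = False
        presence[150:300, :5] = False
        presence[150:300, 5:] = True
        m = matrix_from_presence(presence)
        scores, _ = ps.pca(m, dims=2)
        g1, g2 = scores[:5, 0], scores[5:, 0]
        assert g1.max() < g2.min() or g2.max() < g1.min()

    def test_duplicated_accessions_identical_coordinates(self):
        rng = np.random.default_rng(6)
        base = rng.random((200, 5)) < 0.5
        presence = np.column_stack([base, base[:, 0]])
        scores, _ = ps.pca(matrix_from_presence(presence), dims=3)
        assert np.allclose(scores[0], scores[5])

    def test_variance_ratio_non_increasing(self, small_matrix):
        _, evr = ps.pca(small_matrix, dims=3)
        assert evr[0] >= evr[1] >= evr[2]

    def test_zero_variance_rejected(self):
        presence = np.ones((10, 5), dtype=bool)
        with pytest.raises(ps.PopStructureError):
            ps.pca(matrix_from_presence(presence), dims=2)

    def test_sign_convention_deterministic(self, small_matrix):
        s1, _ = ps.pca(small_matrix, dims=3)
        s2, _ = ps.pca(small_matrix, dims=3)
        assert np.allclose(s1, s2)


class TestVennPartition:
    def test_cell_assignment(self):
        presence = np.array([
            [1, 1, 0, 0, 0, 0],  # L1 only
            [0, 0, 1, 0, 0, 0],  # L2 only
            [1, 0, 1, 0, 0, 0],  # L1&L2
            [1, 0, 0, 0, 1, 1],  # L1&L3
            [1, 1, 1, 1, 1, 1],  # all three (occupancy n; still a valid cell test)
        ], dtype=bool)
        labels = {"a0": "L1", "a1": "L1", "a2": "L2", "a3": "L2",
                  "a4": "L3", "a5": "L3"}
        counts, pct = ps.venn_partition(matrix_from_presence(presence), labels)
        assert counts["L1"] == 1 and counts["L2"] == 1
        assert counts["L1&L2"] == 1 and counts["L1&L3"] == 1
        assert counts["L1&L2&L3"] == 1
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_unlabeled_rejected(self, small_matrix):
        with pytest.raises(ps.PopStructureError):
            ps.venn_partition(small_matrix, {})

    def test_lineage_specific_share_matches_truth(self):
        # within_diversity=0: every lineage-specific k-mer stems from a
        # founder-private variant; compare against a founder-set oracle
        cfg = sd.PanelConfig(n_per_lineage=(3, 3, 3), genome_length=30_000,
                             divergence=0.01, within_diversity=0.0, seed=31, k=31)
        panel = sd.simulate_panel(cfg)
        kc = ke.KmerConfig(k=31, min_count=1)
        sets = [ke.count_kmers(a.sequence_list(), kc, a.accession_id)
                for a in panel.accessions]
        m = ke.build_matrix(sets)
        counts, pct = ps.venn_partition(m, panel.truth.lineage_of)
        founder_kmers = {
            lin: set(ke.count_kmers(
                [ke.codes_to_seq(v) for v in panel.founders[lin].values()], kc).strings())
            for lin in ("L1", "L2", "L3")
        }
        union = set().union(*founder_kmers.values())
        matrix_rows = set(m.row_strings())
        expected_specific = sum(
            1 for km in matrix_rows
            if sum(km in founder_kmers[lin] for lin in founder_kmers) == 1)
        got_specific = counts["L1"] + counts["L2"] + counts["L3"]
        assert got_specific == expected_specific


class TestFst:
    def test_opposite_fixation_gives_one(self):
        calls = np.array([[0, 0, 2, 2]] * 5, dtype=np.int8)
        gm = make_gm(np.arange(1, 6), calls)
        pops = {"p1": ["a0", "a1"], "p2": ["a2", "a3"]}
        wins = ps.fst_windows(gm, pops, window=10, step=10)[("p1", "p2")]
        assert wins[0].fst == pytest.approx(1.0)

    def test_duplicated_population_near_zero(self):
        rng = np.random.default_rng(7)
        col = rng.integers(0, 3, size=(50, 10)).astype(np.int8)
        calls = np.column_stack([col, col])
        gm = make_gm(np.arange(1, 51), calls)
        pops = {"p1": [f"a{i}" for i in range(10)],
                "p2": [f"a{i}" for i in range(10, 20)]}
        fst = ps.fst_global(gm, pops)
        assert fst <= 0.02

    def test_matches_handcoded_oracle_on_toy_table(self):
        # printed 2-population, 5-site toy table
        calls = np.array([
            [0, 0, 1, 2, 2, 2],
            [0, 1, 1, 1, 2, 0],
            [2, 2, 2, 0, 0, 0],
            [0, 0, 0, 0, 0, 2],
            [1, 1, 0, 2, 1, 2],
        ], dtype=np.int8)
        gm = make_gm(np.arange(1, 6), calls)
        pops = {"p1": ["a0", "a1", "a2"], "p2": ["a3", "a4", "a5"]}
        wins = ps.fst_windows(gm, pops, window=100, step=100)[("p1", "p2")]
        num = den = 0.0
        for row in calls:
            a, b, c = wc_oracle_site([list(row[:3]), list(row[3:])])
            num += a
            den += a + b + c
        assert wins[0].fst == pytest.approx(num / den)
        assert wins[0].n_sites == 5

    def test_window_step_layout(self):
        rng = np.random.default_rng(8)
        calls = rng.integers(0, 3, size=(100, 8)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 3_000_001), 100, replace=False))
        gm = make_gm(pos, calls)
        pops = {"p1": [f"a{i}" for i in range(4)],
                "p2": [f"a{i}" for i in range(4, 8)]}
        wins = ps.fst_windows(gm, pops, window=1_000_000, step=100_000)[("p1", "p2")]
        starts = [w.start for w in wins]
        assert all((s - 1) % 100_000 == 0 for s in starts)
        assert all(w.end == w.start + 1_000_000 - 1 for w in wins)

    def test_divergence_sweep_monotonic(self):
        vals = []
        for d in (0.002, 0.01, 0.05):
            cfg = sd.PanelConfig(n_per_lineage=(10, 10, 0), genome_length=20_000,
                                 divergence=d, within_diversity=0.002, seed=32, k=31)
            panel = sd.simulate_panel(cfg)
            gm = panel.genotype_matrix()
            pops = {"L1": [a for a in panel.accession_ids if a.startswith("L1")],
                    "L2": [a for a in panel.accession_ids if a.startswith("L2")]}
            vals.append(ps.fst_global(gm, pops))
        assert vals[0] < vals[1] < vals[2]

    def test_merged_then_split_small(self):
        rng = np.random.default_rng(9)
        # one panmictic pool of 40 split arbitrarily
        freqs = rng.uniform(0.1, 0.9, 200)
        calls = (rng.random((200, 40)) < freqs[:, None]).astype(np.int8) * 2
        gm = make_gm(np.arange(1, 201), calls)
        pops = {"p1": [f"a{i}" for i in range(20)],
                "p2": [f"a{i}" for i in range(20, 40)]}
        assert ps.fst_global(gm, pops) <= 0.02

    def test_bad_window_rejected(self):
        gm = make_gm([1], np.zeros((1, 4)))
        with pytest.raises(ps.PopStructureError):
            ps.fst_windows(gm, {"p1": ["a0", "a1"], "p2": ["a2", "a3"]}, window=0)


class TestLdDecay:
    def test_duplicated_site_perfect_ld(self):
        rng = np.random.default_rng(10)
        col = (rng.random(30) < 0.5).astype(np.int8) * 2
        calls = np.vstack([col, col])  # (2 sites, 30 accessions)
        gm = make_gm([100, 200], calls)
        bins, _ = ps.ld_decay(gm, max_dist=1000, bin_size=1000)
        assert bins[0].mean_r2 == pytest.approx(1.0)

    def test_independent_sites_null_expectation(self):
        rng = np.random.default_rng(11)
        n = 60
        sites = 80
        calls = (rng.random((sites, n)) < 0.5).astype(np.int8) * 2
        gm = make_gm(np.arange(1, sites + 1) * 10, calls)
        bins, _ = ps.ld_decay(gm, max_dist=10_000, bin_size=10_000)
        vals = bins[0]
        # E[r^2] ~ 1/n under independence; 3-SE check with empirical SD
        r2s = []
        z = (calls - calls.mean(1, keepdims=True)) / calls.std(1, keepdims=True)
        r = (z @ z.T) / n
        iu = np.triu_indices(sites, 1)
        r2s = (r**2)[iu]
        se = r2s.std(ddof=1) / np.sqrt(len(r2s))
        assert abs(vals.mean_r2 - 1 / n) < 3 * se

    def test_block_structure_decays(self):
        # accessions are block mosaics of two haplotypes -> nearby sites
        # correlated, distant sites not
        rng = np.random.default_rng(12)
        n, sites, block = 40, 120, 20
        hapA = (rng.random(sites) < 0.5).astype(np.int8) * 2
        hapB = 2 - hapA
        calls = np.empty((sites, n), dtype=np.int8)
        for j in range(n):
            hap = rng.integers(0, 2)
            for b0 in range(0, sites, block):
                if rng.random() < 0.5:
                    hap = 1 - hap
                seg = hapA if hap == 0 else hapB
                calls[b0:b0 + block, j] = seg[b0:b0 + block]
        pos = np.arange(1, sites + 1) * 1000
        gm = make_gm(pos, calls)
        bins, decay_at = ps.ld_decay(gm, max_dist=120_000, bin_size=20_000)
        means = [b.mean_r2 for b in sorted(bins, key=lambda b: b.low)]
        assert means[0] > means[-1]
        from scipy.stats import spearmanr
        rho, _ = spearmanr(range(len(means)), means)
        assert rho < 0

    def test_region_labels(self):
        rng = np.random.default_rng(13)
        calls = (rng.random((40, 20)) < 0.5).astype(np.int8) * 2
        gm = make_gm(np.arange(1, 41) * 100, calls)
        regions = [("c1", 1, 2000, "R1"), ("c1", 2001, 4000, "R3")]
        bins, decay = ps.ld_decay(gm, max_dist=4000, bin_size=500, regions=regions)
        assert {b.region for b in bins} == {"R1", "R3"}
        assert set(decay) == {"R1", "R3"}
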