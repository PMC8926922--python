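"""Shared fixtures: one small 3-lineage panel reused across test modules."""

import numpy as np
import pytest

from kmerwas import kmer_engine as ke
from kmerwas import synthetic_data as sd

RC = str.maketrans("ACGT", "TGCA")


def revcomp_str(s: str) -> str:
    return s.translate(RC)[::-1]


def naive_canonical(kmer: str) -> str:
    rc = revcomp_str(kmer)
    return kmer if kmer <= rc else rc


def naive_count(seqs, k, min_count):
    """Dictionary-of-windows counting oracle."""
    from collections import Counter

    counts = Counter()
    for s in seqs:
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            if set(w) <= set("ACGT"):
                counts[naive_canonical(w)] += 1
    return {km for km, c in counts.items() if c >= min_count}


def make_kmerset(accession_id, kmers, k):
    """Build a KmerSet from explicit k-mer strings (canonicalized)."""
    packed = sorted({ke.string_to_packed(naive_canonical(km)) for km in kmers})
    arr = np.array(packed, dtype=f"S{ke.packed_width(k)}")
    return ke.KmerSet(accession_id, k, arr)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def small_panel():
    """12-accession, 3-lineage panel with a planted causal haplotype (k=31)."""
    cfg = sd.PanelConfig(
        n_per_lineage=(4, 4, 4), genome_length=30_000, n_chromosomes=1,
        divergence=0.01, within_diversity=0.001, het_fraction=0.0, seed=11,
        k=31, causal_length=600, causal_mut_rate=0.02, causal_effect=3.0,
        causal_carrier_fraction=0.4,
    )
    return sd.simulate_panel(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_panel):
    sets = [
        ke.count_kmers(a.sequence_list(), ke.KmerConfig(k=31, min_count=1),
                       a.accession_id)
        for a in small_panel.accessions
    ]
    return ke.build_matrix(sets)
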