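# kmerwas

k-mer presence/absence panel genomics: from raw per-accession sequence to
population structure, association mapping and lineage painting, with a
fully synthetic data generator so the entire pipeline is testable without
external datasets.

## Pipeline stages

| Module | What it does |
| --- | --- |
| `kmerwas.synthetic_data` | Simulates a diploid panel drawn from three diverged lineages (star phylogeny from one ancestor), with lineage-private variation, a planted causal haplotype driving a quantitative phenotype, residual heterozygosity, duplicate accessions, read shredding at chosen coverage, and donor-mosaic chromosomes — all with an exact truth ledger. |
| `kmerwas.kmer_engine` | Canonical k-mer counting (default k = 51, within-accession multiplicity ≥ 2), presence/absence matrix construction with the occupancy filter (rows kept only when present in 2 … n−2 accessions), uniform row sampling, binary + TSV serialization. |
| `kmerwas.panel_qc` | Windowed SNP subsampling (100 per 4-Mb window), pairwise identity-by-state to flag redundant accessions (> 99.5% identity), heterozygous-fraction screening (> 0.1 flagged), and non-redundant set selection. |
| `kmerwas.pop_structure` | UPGMA phylogeny with bootstrap supports (Newick output), PCA of accessions in k-mer space, 3-set Venn partition of lineage k-mer sharing, sliding-window Weir–Cockerham F\_ST, and composite-r² LD decay with region labels. |
| `kmerwas.kmer_gwas` | Pearson-correlation prefilter (\|r\| > 0.2), nested-model likelihood-ratio scores with PCA covariates (association score = −log10 p), effective-variant Bonferroni threshold (tested k-mers / k), exact k-mer placement on reference or de novo targets, and Manhattan-style plot tables (10-kb blocks or anchored-scaffold x axis). |
| `kmerwas.assembly_anchor` | Orders de novo scaffolds along a reference by their longest PAF alignment hit; includes an exact-match seed-and-extend aligner for desk-scale synthetic inputs. |
| `kmerwas.lineage_paint` | Single-locus ("usable") k-mer detection, lineage-specific k-mer sets, 100-kb segment assignment of a target (hexaploid-like) chromosome to its donor lineage (20% usable-present floor, 0.01% winning margin), and per-chromosome contribution summaries. |
| `kmerwas.genotypes` | Shared biallelic genotype matrix type with plain-text VCF input/output. |

## CLI

One entry point, `kmerwas`, grouped by stage:

```bash
# simulate a panel (config is a JSON PanelConfig), phenotypes, reads, mosaics
kmerwas simulate panel --config cfg.json --seed 1 --out panel/
kmerwas simulate phenotype --truth panel/truth.json --noise-sd 1 --out pheno.tsv
kmerwas simulate reads --fasta acc.fasta --coverage 5 --out reads.fasta

# k-mer counting and matrix
kmerwas kmers count --fasta acc.fasta --k 51 --min-count 2
kmerwas kmers matrix --fasta a.fasta --fasta b.fasta ... --out matrix.bin
kmerwas kmers sample --matrix matrix.bin --n 100000 --seed 1 --out sample.bin

# QC, structure, diversity
kmerwas qc --vcf calls.vcf --ibs-threshold 99.5 --het-threshold 0.1 --out qc/
kmerwas tree --matrix sample.bin --bootstraps 100 --seed 1 --out tree.nwk
kmerwas pca --matrix sample.bin --dims 3 --out pcs.tsv
kmerwas fst --vcf calls.vcf --pops pops.tsv --window 1000000 --step 100000 --out fst.tsv
kmerwas ld --vcf calls.vcf --max-dist 5000000 --regions regions.bed --out ld.tsv

# association mapping, anchoring, painting
kmerwas gwas --matrix matrix.bin --pheno pheno.tsv --pcs 3 --ref ref.fasta --out gwas/
kmerwas anchor --paf aln.paf --out anchors.tsv
kmerwas paint --assembly hex.fasta --chroms 1D,2D --matrix matrix.bin \
    --labels lineages.tsv --segment 100000 --out paint/
```

All stages are importable as plain functions; the CLI is a thin wrapper.

## Notes

- k-mers are strand-collapsed to canonical form (lexicographic minimum of
  k-mer and reverse complement); k must be odd.
- The presence/absence matrix stores 2-bit-packed k-mers; desk-scale
  panels (tens of accessions × megabase genomes) run in a few GB of RAM.
- Genotype inputs are plain-text VCF; scaffold alignments are 12-column
  PAF; painting output is BED plus a summary TSV.
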