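# heteropool

Genomic analyses of heterotic gene-pool development in a hybrid crop,
implemented as a tested, reusable pipeline and exercised end-to-end on
synthetic data with known truth. Given a three-group diversity panel — an
open-pollinated progenitor group (OPV) and two inbred heterotic pools
(maintainer **B**, restorer **R**) — the package provides:

- **variant_io** — VCF input, the high-confidence biallelic-SNP filter
  suite (QUAL > 30, site heterozygosity < 0.3, genotype DP > 1, site mean
  depth in (1, 16), SNPs only, strand balance SAR & SAF > 0, read
  placement RPL & RPR > 1, MAF > 0.05, missing < 0.3), per-group allele
  frequencies and heterozygosity.
- **popdiff** — per-site Weir & Cockerham (1984) F_ST variance components
  between group pairs, 500-kb windowed scans by summing numerator and
  denominator over markers, top-5% window flagging, greedy LD pruning
  (r² > 0.2), PCA on standardized dosages, and keyword candidate-gene
  extraction from high-F_ST 100-kb windows.
- **gene_depth** — per-gene mean read depth, three-state copy
  classification (absent = zero depth, amplified = more than 3x the
  sample's median gene depth, otherwise present), per-sample/per-gene
  PAV summaries, B-vs-R gene-content differentiation with a group-label
  permutation null, nested depth/group regression of absent-gene counts,
  gene-length bias, and PAV PCA.
- **introgression_overlap** — per-gene introgression values (max ancestry
  of overlapping track windows), introgressed classification at the 0.1
  threshold, and chi-squared enrichment of gene absence inside
  introgressed regions.
- **heterosis** — classification of ancestral OPV variation (alternate
  frequency in [0.25, 0.75]) into parallel vs opposite sorting when both
  pools shifted by at least 0.2, windowed opposite-shift rates, and
  in-silico cross complementation (shared-absent gene counts between
  random parent pairs within/between groups).
- **synthetic_data** — a seeded generator producing the whole input
  bundle (VCF, GFF3 gene models, gene-depth TSV, BED ancestry track,
  sample table) plus a complete truth ledger: true shift categories and
  group frequencies, true copy numbers, planted introgression blocks and
  deletions, per-sample coverage.
- **pipeline_cli** — one-command orchestration with a YAML config,
  manifest, and summary report.

## Command line

```bash
# generate a synthetic panel with truth ledger
heteropool simulate --out sim/ --seed 7

# full pipeline from a YAML config (simulates when no inputs are given)
heteropool run --config run.yaml

# individual stages
heteropool filter --vcf sim/panel.vcf --samples sim/samples.tsv \
    --out filtered.vcf --report report.tsv
heteropool fst --vcf filtered.vcf --samples sim/samples.tsv \
    --pair B,R --window 500000 --out windows.tsv
heteropool pca --vcf filtered.vcf --samples sim/samples.tsv \
    --subsample 0.01 --r2 0.2 --seed 7 --out scores.tsv
heteropool pav --depth sim/gene_depth.tsv --genes sim/genes.gff3 \
    --out states.tsv
heteropool pav-test --depth sim/gene_depth.tsv --genes sim/genes.gff3 \
    --samples sim/samples.tsv --threshold 0.2 --n-perm 999 --seed 7
heteropool introgression --track sim/ancestry.bed --genes sim/genes.gff3 \
    --depth sim/gene_depth.tsv --sample R001
heteropool heterosis --vcf filtered.vcf --samples sim/samples.tsv \
    --band 0.25,0.75 --min-shift 0.2 --out shifts.tsv
heteropool crosses --depth sim/gene_depth.tsv --genes sim/genes.gff3 \
    --samples sim/samples.tsv --n 500 --seed 7 --out crosses.tsv
```

A minimal `run.yaml`:

```yaml
out_dir: run1
seed: 7
simulate:
  n_sites: 30000
n_crosses_per_type: 200
```

## Conventions

Genomic intervals are 0-based half-open internally; VCF positions are
1-based and GFF3 intervals 1-based inclusive, converted at the I/O
boundary. Windows are anchored at position 0 of each chromosome. All
randomness flows from explicit seeds; identical config + seed gives
byte-identical outputs.
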