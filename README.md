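# poolscan

Pooled-sequencing (pool-seq) differentiation mapping between
phenotype-by-genotype groups: absolute allele frequency difference (AFD)
genome scans, sliding-window smoothing, candidate-region and gene
extraction, a Monte-Carlo Hardy–Weinberg genotype-deviance test, and
cross-population allele-frequency panels — plus a forward simulator of
the underlying two-locus study design so the whole pipeline is testable
without any external data.

## What it does

- **poolio** — read/write samtools mpileup text, popoolation2-style sync
  count tables, GFF3 gene annotation, and commented TSV result tables
  (plain or gzipped input).
- **scan** — biallelic SNP calling from two pools, inclusive depth
  bounds and pooled-count MAF filters, per-SNP AFD (half the L1 distance
  between allele-frequency vectors), 40 kb / 20 kb sliding-window means
  (≥ 6 SNPs per window), top-k SNP ranking, and 180 kb candidate regions
  centred on SNPs or SNP clusters.
- **annotate** — intersect candidate regions with gene annotation and
  flag genes by case-insensitive keyword search over names/attributes
  (default keywords: bone, ectoderm, tumor necrosis factor, wnt).
- **hwetest** — Hardy–Weinberg expected genotype proportions, the
  genotype-frequency deviance statistic, and its upper-tail Monte-Carlo
  randomization test (add-one p-value estimator; exact trinomial
  enumeration available for small panels).
- **simdata** — forward simulation: a major locus fully determining
  low/heterozygous/complete classes, a modifier locus shifting
  heterozygotes between complete and partial morphs via a penetrance
  table, exponential-decay linked neutral SNPs, Poisson depth, binomial
  read sampling, and uniform sequencing error.
- **popfreq** — panels of fixed (AFD = 1) or high-AFD flanking SNPs,
  oriented to the reduced-plating allele, with per-population frequency
  tables.

## CLI

```sh
# simulate the four-pool design and write sync/truth/individuals files
poolscan simulate --seed 1 --out-prefix out/sim

# Complete^CC vs Low^LL scan (pools 1,2; depth 40-130, MAF >= 0.2)
poolscan scan --sync out/sim.sync --pools 1,2 --depth-min 40 --depth-max 130 \
    --out-prefix out/cc_ll

# Complete^CL vs Partial^CL scan (pools 3,4; depth 40-200)
poolscan scan --sync out/sim.sync --pools 3,4 --depth-min 40 --depth-max 200 \
    --out-prefix out/cl_cl

# candidate-gene annotation of the scan's regions table
poolscan annotate --gff genes.gff3 --regions out/cl_cl.regions.tsv --out out/genes.tsv

# allele panels and their frequencies in other population pools
poolscan panel --scan out/cc_ll.snps.tsv --mode fixed --reduced-pool 2 --out out/panel.tsv
poolscan panel-freq --panel out/panel.tsv --pools marine=marine.sync --out out/freqs.tsv

# Hardy-Weinberg deviance randomization test (counts are PP,PC,CC)
poolscan hwe-test --counts 10,25,11 --freq 0.583 --iters 9999 --seed 1

# or run a whole configured pipeline
poolscan run --config pipeline.yaml --seed 1 --outdir out/
```

Exit codes: 0 ok, 2 configuration error, 3 input format error.

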