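# gradedpool

QTL mapping from whole-genome sequencing of **graded-pool F2 bulks** — a
generalisation of two-tail bulked-segregant analysis in which an F2
population is ranked by phenotype, split into k >= 2 ordinal bulks, and
each bulk sequenced once as a DNA pool.  The package is aimed at plant
geneticists and breeders who have a multi-sample VCF of pooled bulks (plus
optionally the two parents) and want candidate QTL intervals, and at
methodologists who want to study the design's power.

## What it computes

At every biallelic SNP the per-bulk read counts form a 2 x k ordered
contingency table (rows: reference / alternate allele; columns: grades).
The default statistic is a **ridit analysis**: with column totals `N_j`,
the ridit of grade j is

    r_j = (sum_{i<j} N_i + N_j/2) / N,

and the two allele rows are compared through their mean ridits — exactly a
tie-corrected Wilcoxon rank-sum test on grouped data (`N r_j + 1/2` is the
shared midrank of grade j), with a two-sided normal p-value.
Kruskal-Wallis and Pearson chi-square comparators are built in.

Because wide crosses produce heavy per-SNP noise, the scan does not
threshold single SNPs: each chromosome is tiled with non-overlapping
400-kb windows and each window is scored by the **fraction of its SNPs
with p < alpha** (windows with fewer than 10 SNPs are skipped).  The
top-ranked windows, with adjacent calls merged, are the candidate QTL
intervals.

Also included:

- a four-stage variant filter (QUAL, median-relative depth,
  parent-informative sites, fixed non-reference sites);
- an **F2 pool-seq simulator** (Haldane recombination, additive +
  dominance QTLs, phenotype-ranked grading with optional
  misclassification, Poisson/binomial read sampling) and a paired-seed
  power harness over coverage, pool size, bulk number, misclassification
  and test statistic;
- the **heterosis-contribution arithmetic** for near-isogenic-line
  comparisons: `(Y_NIL - Y_parent) / (Y_F1 - Y_parent)` plus pooled-MSE
  standard errors of pairwise line differences from summary statistics.

## Worked example

Simulate a small experiment with one planted QTL, then scan it:

```sh
$ gps fixtures --out-dir demo --scenario single_qtl --seed 3
$ gps scan --vcf demo/single_qtl.vcf --design demo/single_qtl.design.tsv \
      --alpha 0.001 --min-snps 5 --top-n 1 --out demo/scan
500 SNPs tested, 20 windows, 1 interval(s) called
  rank 1: chr1:1200000-1600000 ratio=1.000 n_snps=27
```

The fixture plants a QTL at chr1:1,400,000 (truth in
`demo/single_qtl.truth.tsv`); the rank-1 400-kb interval
`chr1:1,200,000-1,600,000` contains it.  `demo/scan.snps.tsv` holds the
per-SNP statistics (`-ln p` column for plotting), `demo/scan.windows.bed`
the per-window ratios, `demo/scan.intervals.bed` the calls, and
`demo/scan.filter_report.tsv` the per-stage filter counts.

Heterosis arithmetic from per-line summaries (`line  n  mean  sd`):

```sh
$ gps heterosis --summaries lines.tsv --f1 F1 --parent FH --nil NIL
NIL: contribution rate 27.9% (fraction 0.2790); yield change vs FH: +9.3%
```

i.e. the NIL recovers 27.9% of the F1-parent yield gap and out-yields the
parent by 9.3%.

Library use mirrors the CLI: `read_bulk_design`, `read_pooled_vcf`,
`run_filters`, `test_track`, `window_ratio`, `call_intervals`, or the
one-call `scan(...)`; the simulator is `SimConfig` / `simulate_f2` /
`pool_reads` / `power_grid`.

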