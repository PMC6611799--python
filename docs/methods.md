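# Methods

## The mapping problem

Graded-pool sequencing generalises two-tail bulked-segregant analysis
(BSA).  An F2 population segregating for a quantitative trait is ranked by
phenotype and partitioned into k >= 2 ordinal bulks ("grades"; grade 1 =
highest phenotype class).  Each bulk is sequenced once as a DNA pool.  At a
SNP linked to a causal locus the high-parent allele frequency rises
monotonically from the low to the high grade; at an unlinked SNP all bulks
sit near 50%.  The per-SNP evidence is an ordinal association test on the
2 x k table of (reference reads, alternate reads) per grade; QTL intervals
are then called from a windowed noise-reduction statistic.

## Per-SNP statistic: ridit analysis

Ridit scores use the combined sample as the reference distribution:
`r_j = (sum_{i<j} N_i + N_j/2) / N`, the cumulative mass below grade j plus
half its own mass.  `N r_j + 1/2` is exactly the midrank shared by every
read in grade j, so the comparison of the two allele rows' mean ridits is a
Wilcoxon rank-sum test on grouped data.  We use the tie-corrected normal
approximation,

    z = (W1 - n1(N+1)/2) / sqrt( n1 n2/12 [ (N+1) - sum_j (N_j^3 - N_j) / (N(N-1)) ] ),

with two-sided p.  Ties dominate (only k distinct values), so the tie
correction is essential; Bross's simple `(1/n1 + 1/n2)/12` mean-ridit
variance is available via `tie_correction=False` for comparison, and is
anti-conservative here.  The implementation works on grouped counts and is
verified in the test suite against a brute-force oracle that expands each
table into individual observations and ranks them independently
(agreement to 1e-12 relative tolerance), and against Monte-Carlo
permutation p-values on small tables.

Comparators evaluated by the same track interface: Kruskal-Wallis with
grades as groups and allele identity as the binary response (tie-corrected
midranks, chi-square reference with k-1 df), and Pearson's chi-square on
the 2 x k table (zero columns dropped with df reduced, no continuity
correction).  For k = 2 the ridit z and the KW H satisfy z^2 = H.

Degenerate tables (an empty allele row, or all reads in one grade) yield
z = 0, p = 1 by convention inside genome scans, so a single odd site never
aborts a run; the scalar chi-square entry point raises instead, which is
the behaviour a direct caller should see.

### Reads as observations, and the effective pool size

The test treats reads as independent draws, which is how the method is
ordinarily applied to pool-seq data and is the package default.  For a
bulk of n diploid individuals sequenced to depth D this is mildly
anti-conservative: the bulk's true allele frequency drifts around the
population value with variance `sigma_d^2 / (4n)` (dosage variance
`sigma_d^2 = 1/2` in an F2), inflating between-bulk contrast variance by
about `1 + D/(2n)` (~1.35 at n = 300, D = 210).  Finite-population terms
cancel for contrasts between disjoint bulks (their sampling covariance is
`-sigma^2/(N-1)`), so the classical pool-seq effective-size scaling —
multiply each bulk's counts by `2n / (2n + D)` — restores calibration.  It
is exposed as `effective_pool=True` on `test_track` and `--effective-pool`
on the CLI, off by default.  Replicate-genome simulations at 3 x 300
individuals and 0.7x per individual measure a significant-SNP fraction at
alpha = 0.05 of ~0.053 with the correction (vs ~0.078 without); the small
residual comes from higher-order terms of the k-group rank statistic.

## Noise reduction and interval calling

Each chromosome is tiled from coordinate 0 with non-overlapping windows
(default 400 kb; a 1-based position p falls in window `floor((p-1)/window)`).
A window's score is the fraction of its SNPs with p below a per-SNP cut
`alpha` (default 1e-3 — unstated upstream, so it is exposed prominently;
the ratio statistic absorbs a permissive cut because background windows
have a near-constant expected fraction).  Windows with fewer than 10 SNPs
are skipped.  Candidate intervals are the top-ranked windows (default top
10, and/or a ratio floor); adjacent called windows merge into one interval
carrying the peak ratio.

Ranking is by ratio descending with ties broken by the window's mean
-ln p, then by significant count, then genome order.  The mean -ln p
tie-break is a deliberate design choice: with a strong QTL and deep pools,
per-SNP power saturates over several Mb, the ratio plateaus at 1.0 across
many windows, and a count-based tie-break would pick the SNP-densest
plateau window.  The per-SNP evidence still peaks at the QTL in
expectation, so ranking inside the plateau by it preserves single-window
resolution whenever the data allow it.  Whenever ratios are untied the
ranking is identical to (ratio, significant count, coordinate).

### Resolution limits

Simulations with a planted QTL of additive effect 0.5 phenotypic SD
(3 bulks x 300 individuals, 0.7x per individual, 12 x 30 Mb chromosomes,
2,000 SNPs each) localize the QTL with the rank-1 400-kb window to within
one window in about 75% of replicates; at 1x per individual this rises to
~83%.  An upper bound computed from the true (noiseless) bulk allele
frequencies is ~90%: the residual peak wander is mostly read-sampling
noise on the window evidence profile, with an irreducible component from
which recombinants land in which bulk.  Cross-window smoothing of the
evidence profile could recover part of the read-noise gap but belongs to
the SNP-index/smoothed-frequency family of methods, which this package
deliberately does not implement.

## Variant filtering

Four stages, in order: (1) QUAL >= min_qual (default 30, a conventional
Phred floor — the upstream choice is unstated); (2) per-pool depth within
a closed window around that pool's median depth (defaults 0.5x-2x,
median-relative to be robust to per-lane coverage differences; medians are
computed on the post-quality table); (3) optionally, both parents
homozygous for different alleles (applied automatically when parent
genotypes are attached, skippable for parent-free runs); (4) drop sites
where every pool shows only non-reference reads (the mirrored all-reference
rule is an off-by-default flag, keeping the default literal).  Only
biallelic SNPs enter the table at all; multi-allelic records are dropped,
not split, because the model is one ref/alt frequency per site.

## The F2 pool-seq simulator

The generator reproduces the experiment end to end with rice-like
defaults: 12 chromosomes of 30 Mb at a uniform 4 cM/Mb, 2,000 uniformly
placed SNPs per chromosome, 900 F2 individuals in three graded bulks of
300, 0.7x sequencing per individual (pool depth ~210x), sequencing-error
rate 0.001.

- **Meiosis**: per gamete, crossover count ~ Poisson(map length in
  Morgans), breakpoints uniform, no interference (Haldane) — the simplest
  standard model, adequate for a power study.
- **Phenotype**: `y = sum_q [ a_q (d_q - 1) + dom_q * 1(d_q = 1) ] +
  N(0, env_sd^2)` with dosage d in {0,1,2} copies of the high-parent
  allele.
- **Grading**: rank by phenotype descending; consecutive fractions of the
  ranked population form grades 1..k (individuals beyond the fraction sum
  stay unassigned).  A boundary mode takes explicit trait cut points
  instead.  Misclassification swaps `floor(m * n_b)` uniformly chosen
  members of a target bulk (or every bulk) with uniformly chosen
  outsiders — a symmetric mechanism chosen for want of a stated one.
- **Reads**: pool depth ~ Poisson(n_b x coverage) per SNP (equal DNA mass
  per individual assumed); alternate reads ~ Binomial(depth,
  f(1-eps) + (1-f)eps) with f the bulk's true pooled frequency.

All randomness fans out from one seed into named substreams (genome,
gametes, phenotype, misclassification, reads), so identical configurations
are bit-reproducible and individual stages can be varied while sharing the
rest.  What the simulator does **not** emulate: polygenic background
beyond the listed QTLs, linked selection between QTLs on one chromosome,
reference bias and mapping error, variable SNP density and recombination
landscapes, overdispersed (non-Poisson) coverage.  Passing tests therefore
demonstrate correctness of the machinery and qualitative behaviour of
power, not real-data error rates.

The power harness evaluates detection as: the rank-1 called interval,
extended by a tolerance of one window per side, contains the QTL.  Cells
of a parameter grid share per-replicate seeds (common random numbers), so
power comparisons along an axis are paired.

## Heterosis arithmetic

A mapped locus's share of hybrid vigour is
`(Y_NIL - Y_parent) / (Y_F1 - Y_parent)` from per-line mean yields — a
dimensionless, affine-invariant ratio reported as a percentage (one
decimal, half-away-from-zero).  Note the ratio computed from the published
rounded group means is 27.898% -> 27.9%, one ulp above the published 27.8%
figure, which was presumably derived from unrounded means.  Pairwise line
comparisons use the one-way layout on summary statistics: pooled
`MSE = sum (n_g - 1) sd_g^2 / sum (n_g - 1)` over all groups and
`SE(I-J) = sqrt(MSE (1/n_I + 1/n_J))`.  Tukey studentized-range p-values
can be added but are flagged approximate (summary-level inputs, unequal
n); they are not computed by default.

## Problem sizes used by the test suite

The acceptance-style simulation tests run at the full standard conditions
(12 chr x 2,000 SNPs, 900 individuals): 20 replicate null genomes for
calibration — averaging replicate genomes is necessary because linkage
gives the single-genome significant-SNP fraction an SD of ~0.009, about
twice the binomial band it is compared against — and 100 planted-QTL
replicates shared across all power cells.  The CLI smoke tests use small
two-chromosome genomes.
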