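# Methods

This note records the models implemented in `methylink`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing
results.

## Global methylation scoring

The per-sample global methylation level is the unweighted mean beta over
array probes annotated to young LINE-1 subfamilies.  A probe qualifies
when its repeat family starts with `L1HS` or `L1PA`, its aligned stretch
is at least 45 bp long, **and** covers at least 90% of the probe sequence
— the two printed thresholds are applied conjunctively, the conservative
reading.  Missing betas are dropped per probe–sample cell, never imputed;
a sample with no observed qualifying probe is an error rather than a
silent NaN.

The WGBS variant retains a repeat element when at least three of its CpGs
are covered by ≥ 10 reads, averages beta over those covered CpGs, and
scores the sample as the *unweighted mean of element means* (not
CpG-weighted), so long elements do not dominate.

## Focal CGI hypermethylation in short PMDs

For each sample, the baseline is the mean μ and standard deviation σ
(n−1 denominator) of that sample's CGI-probe betas inside the merged
HMDs; the count is the number of promoter-flagged CGI probes inside
short PMDs with beta strictly greater than μ + 2σ.  Whether the baseline
uses all CGI probes or promoter CGI probes only is genuinely open; the
default uses all CGI probes in merged HMDs, with
`promoter_only_baseline=True` to restrict.  Ties exactly at μ + 2σ are
not counted (strict inequality).

## Domain merging and PMD subclasses

PMD/HMD calls arrive as 100-kb units.  Maximal runs of adjacent same-type
units (adjacent = end equals next start) are merged; merged domains of
length ≤ 300 kb are dropped (strict `> 300 kb`), and a log line accounts
for the dropped length.  Merged features are unweighted means of the
constituent units (units share one width, so this equals the
length-weighted mean).  Merging is idempotent.

Merged PMDs are subclassified by agglomerative Ward clustering on
standardized (methylation variability, replication timing), cut at k = 3.
Inputs are sorted by (chrom, start) before linkage so labels are
reproducible.  The "short PMD" subclass is the cluster with the smallest
median genomic length — an operational definition that matches the
observation that shorter PMDs replicate earlier.

## Replication timing

Per-cell-line 5-kb signal (higher = earlier replication) is z-scaled,
then quantile-normalized against the mean of the per-line sorted
distributions; ties receive the mean reference value of their tied
positions.  Windows missing in any line are excluded *before*
normalization.  Each window gets an equal-variance two-sample Student's
*t* (cancer minus normal; positive t = earlier in cancer).  Windows with
zero pooled variance and equal means are flagged and reported as t = 0,
P = 1.

Genes inherit every window their body overlaps (any-overlap; a
majority-overlap variant was considered and rejected since gene bodies
"spanning" windows is the natural reading).  Multi-window genes combine P
values by Fisher's method (X² = −2Σln p, df = 2k; zeros floored at the
smallest positive double so the statistic stays finite) and average the t
statistics.  Bonferroni runs over genes with ≥ 1 window only.  A gene is
`late_in_cancer` when adjusted P < 0.05 with negative mean t,
`early_in_cancer` for the opposite sign.

## Aneuploidy

A segment qualifies when |log₂ ratio| ≥ 0.2 (inclusive by default; the
printed "± 0.2" does not state strictness, and a `strict` flag flips it)
and it covers ≥ 10% of an arm it touches or ≥ 5% of its chromosome.  The
level is Σ |log₂| × length over qualifying segments with length
normalized by the total autosome length: normalization affects scale
only, not ranking, and makes the score genome-size independent (a
half-genome event at |log₂| = 0.5 scores 0.25).  Sex chromosomes are
excluded by default.

## Association models

Per-gene OLS shares one design matrix across genes, so the fit is
vectorized exactly (pseudo-inverse once, per-gene residual variance).
Wald z = coef/SE with two-sided P from the t distribution on n − p df;
BH-FDR is applied per predictor across genes at 0.05.  Tumour stage
enters as a single ordinal covariate (I–IV → 1–4) and is included only
when enough staged samples exist (the pipeline requires 100).  Mutation
burden enters as log₁₀(1 + n) by default (raw via flag): burdens are
right-skewed counts and the log keeps leverage bounded.

Preranked enrichment uses the weighted running-sum statistic (hit weight
= |score|, exponent 1; miss penalty uniform), ES = signed extremum of the
walk.  When a set covers the whole universe the miss term degenerates; we
use the uniform ECDF so the walk ends at 0 and report the intermediate
extremum.  The null permutes gene labels (draws random same-size sets) —
with only a ranking available, sample permutation is not an option.  NES
divides ES by the mean |null ES| of matching sign; FDR is the standard
positive/negative-tail ratio over pooled normalized nulls, clipped at 1.
Defaults: 1,000 permutations, minimum set size 10, report threshold
FDR < 0.25.

The enrichment stage of the pipeline ranks genes by the
*demethylation*-association z (the negated global-methylation
coefficient z), so gene sets repressed upon methylation loss appear at
the negative extreme (NES < 0).  This is purely a sign convention; the
regression itself uses the methylation level as the predictor.

ssGSEA scores one sample by ranking genes by expression and summing the
difference between the rank-weighted ECDF of set genes (weight =
rank^α, α = 0.25, the conventional exponent) and the uniform ECDF of
non-set genes; being rank-based it is invariant to monotone transforms
of expression.

Partial Spearman correlation is first-order: rank all three vectors and
apply (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)), with the t approximation
on n − 3 df.  The immune-specificity filter flags genes whose mean
expression in leukocytes + lymph nodes is ≥ 5× the mean of the remaining
tissues (pseudocount 1e-8 in the denominator).  Repeat expression is
normalized to rates by total aligned reads and z-standardized within
tumour type; single-sample types are NaN rather than zero.

## Boundary proximity test

A gene's distance to the nearest HMD is the minimum gap in bp between
its body and any HMD interval (0 when overlapping), measured edge to
edge — the claim under test concerns bodies near boundaries, not
midpoints.  The observed statistic is the mean over the test set; the
null redraws equally sized sets uniformly *without replacement* from the
PMD gene universe (a draw is a gene set).  Distances are computed against
the original 100-kb HMD units by default (a flag-free choice: callers may
pass merged HMDs instead).  The empirical one-sided P (smaller distance =
concentration near boundaries) uses add-one smoothing,
(1 + #{null ≤ obs})/(1 + n_perm), so it is never exactly 0.  Null draws
are vectorized (argpartition of random keys), making 10,000 draws cheap.

## Survival and response

PFS is internally in days (1 month = 30.44 days).  DCB = PR, or SD
lasting strictly more than 6 months; PD or SD ≤ 6 months = NDB.  The
median split sends exact ties to the low group (configurable; the
convention has to be fixed somewhere and ties-low keeps the low group
non-empty for odd n).  Percentile stratification labels < 30th percentile
low and > 70th high, excluding the middle.  Kaplan–Meier, the two-group
log-rank test and Cox models are delegated to `lifelines`; Cox uses the
Efron tie correction (the default of the statistical environments this
kind of analysis is usually run in), which coincides with Breslow on
tie-free data.  Logistic response models use statsmodels maximum
likelihood; quasi-separation surfaces as large standard errors and is
flagged, not masked.

## Synthetic-data generator

One latent factor d ~ Uniform(0, 1) per sample encodes demethylation
extent.  Couplings and defaults:

| layer | model | default |
|---|---|---|
| open-sea L1 betas | base − effect·d + N(0, σ), clipped to [0.001, 0.999] | base 0.75, effect 0.25, σ 0.05 |
| HMD CGI betas | base + N(0, σ) | base 0.10 |
| short-PMD promoter CGI | hypermethylated (+0.5) with prob = rate·d | rate 0.4 |
| mutation burden | Poisson(exp(ln 30 + link·(d − ½))) | link 1.5 |
| CN events | Poisson(0.3 + link·d) arm-scale segments, |log₂| ≥ 0.25 | link 5 |
| immune expression | N(0,1) − effect·z(d) for 77 planted genes | effect 1.5 |
| survival | exponential, HR = `planted_hr` for the low-score group | HR 2, median PFS 180 d (high group) |

The low/high groups come from the median of the *realized* global score,
matching the cohort convention; administrative censoring at a horizon
solved (Brent) to give ≈ 30% censoring.  Domains tile three synthetic
chromosomes (60/45/30 Mb) with alternating HMD runs and PMDs planted in
three subclasses — short (400–800 kb, early), mid, long (1.5–3 Mb, late)
— plus ≤ 300 kb runs that the merge filter must drop.  Immune genes are
placed 5–60 kb from short-PMD edges; other PMD genes are uniform in
PMDs.  Replication tracks put smoothed random-walk signal on a 5-kb grid
for 5 normal and 10 cancer pseudo cell lines, subtract a planted shift
(default 1.5 in z units, noise SD 0.4) from cancer lines over designated
late genes, and blank a small fraction of cells to exercise
missing-window exclusion.  The default cohort size (141) matches the
combined clinical cohort the pipeline is aimed at; effect sizes linking
d to each layer are free parameters of the generator documented here,
not claims about biology.

All randomness flows from a single `numpy` generator seeded by the
config: identical configs give bit-identical bundles.

What the generator does **not** emulate: probe chemistry and IDAT-level
noise, batch effects, purity-driven signal mixing (purity is simulated
independent of d), correlated gene–gene expression structure, subclonal
copy number, and informative censoring.  Passing tests therefore show
that the estimators recover planted structure under idealized noise, not
that they are robust to those real-data artefacts.

## Problem sizes and calibration checks

The test suite and `scripts/acceptance.py` use: 100 cohorts of n = 400
for Cox coverage of the planted log-HR (±3 SE, ≥ 95% expected); 5 runs of
1,000 null genes at n = 200 for regression type-I (raw P < 0.05 rate
within [0.035, 0.065]; BH discoveries ≪ 1 per run on average); 500
random instances for Fisher-combination agreement with the independent
`gammaincc` upper tail (≤ 1e-10); 50 instances of ≤ 20 genes for exact
brute-force agreement of the enrichment running sum; 200 null
repetitions at 2,000 permutations for proximity-P uniformity (KS) plus
20 planted cohorts for power; and the default 141-sample cohort for
end-to-end direction recovery.  The permutation count 2,000 is a
scaled-down version of the 10,000-draw default used for single
analyses.

## Known limitations

- The pipeline's short-PMD definition depends on the k = 3 cut
  recovering the planted structure; on real data the subclass count
  should be inspected, not assumed.
- The preranked FDR uses the pooled-null ratio estimator, which is noisy
  with few gene sets; with a single set it effectively reduces to the
  permutation P.
- `fit_gene_models` assumes one complete design across genes; per-gene
  missing expression is not masked (rows with missing predictors are
  dropped for all genes).
- Distances in the proximity test ignore chromosome ends: a gene on a
  chromosome without any HMD gets infinite distance and would poison the
  mean; the generator never produces this, but real inputs should be
  filtered.
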