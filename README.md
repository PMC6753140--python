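# methylink

Tools for linking genome-wide DNA methylation loss to immune-gene
repression and immunotherapy outcome in tumour cohorts.

Rapidly dividing tumours progressively lose CpG methylation in
late-replicating DNA, forming partially methylated domains (PMDs), while
gaining focal methylation at CpG-island (CGI) promoters.  Because many
immunomodulatory genes sit inside short PMDs close to highly methylated
domain (HMD) boundaries, this coupled loss/gain can silence immune
pathways — so a globally demethylated tumour may resist checkpoint
blockade even when its mutation burden is high.  `methylink` implements
the quantitative machinery needed to test this on methylation-array,
copy-number, expression and clinical tables:

- **Global methylation score** — the mean beta value over array probes
  whose sequence maps ≥ 90% (and ≥ 45 bp) to young LINE-1 subfamilies
  (L1HS/L1PA); a WGBS element-level variant (≥ 3 CpGs at ≥ 10× coverage)
  for validation.
- **PMD handling** — merge 100-kb PMD/HMD unit calls, keep merged domains
  > 300 kb, subclassify PMDs by Ward clustering on (methylation
  variability, replication timing), and count promoter-CGI probes in
  short PMDs whose beta exceeds the sample's HMD-CGI baseline by > 2 SD.
- **Replication timing** — z-scale + quantile-normalize per-cell-line
  5-kb Repli-seq signal, per-window Student's *t* (cancer vs normal),
  per-gene Fisher-combined *P* with mean *t* and Bonferroni classification
  into earlier/later-replicating in cancer.
- **Aneuploidy level** — Σ |log₂ ratio| × length over segments with
  |log₂| ≥ 0.2 covering ≥ 10% of an arm or ≥ 5% of a chromosome
  (length-normalized by the autosome total).
- **Association models** — per-gene OLS of expression on global
  methylation, mutation burden, aneuploidy, purity, age and stage
  (`y ~ β₁·meth + β₂·burden + β₃·aneuploidy + β₄·purity + β₅·age +
  β₆·stage`), BH FDR per predictor; preranked enrichment (weighted
  running-sum ES, permutation NES/FDR), ssGSEA-style single-sample
  scores, first-order partial Spearman correlation, the 5-fold
  immune-tissue specificity filter, repeat-expression normalization.
- **Boundary proximity** — permutation test (default 10,000 draws) of
  whether a gene set inside PMDs lies closer to HMDs than random PMD
  genes.
- **Survival & response** — DCB/NDB calls (PR, or SD > 6 months), median
  or 30/70-percentile stratification, Kaplan–Meier + log-rank, Cox
  proportional hazards (Efron ties), logistic response models.
- **Synthetic cohorts** — a generator that plants a latent per-sample
  demethylation factor coupling all of the layers above, so the whole
  pipeline is testable end to end without access to patient data.

## Worked example

```python
from methylink import PipelineConfig, run_pipeline

cfg = PipelineConfig(outdir="demo_out", seed=1234,
                     n_perm_proximity=2000, n_perm_enrichment=1000)
res = run_pipeline(cfg)

surv = res["stages"]["survival"]
print(f"HR (low vs high methylation) = {surv['hr_low_vs_high']:.2f}, "
      f"log-rank P = {surv['logrank_p']:.2g}")
assoc = res["stages"]["association"]
print(f"immune set NES = {assoc['immune_nes']:.2f}, FDR = {assoc['immune_fdr']:.2g}")
prox = res["stages"]["proximity"]
print(f"mean distance to nearest HMD: observed {prox['observed_mean_distance_bp']/1e3:.0f} kb "
      f"vs null {prox['null_mean_bp']/1e3:.0f} kb, P = {prox['p_empirical']:.2g}")
```

prints

```
HR (low vs high methylation) = 2.30, log-rank P = 3.9e-05
immune set NES = -2.51, FDR = 0
mean distance to nearest HMD: observed 30 kb vs null 334 kb, P = 0.0005
```

The simulated cohort (141 samples) plants a hazard ratio of 2 for the
demethylated half; the Cox estimate of 2.30 is within sampling error of
that truth.  The planted immune gene set ranks at the repressed extreme
of the demethylation-association ranking (negative NES at FDR < 0.25),
and immune genes sit an order of magnitude closer to HMD boundaries than
random PMD genes.  The same stages are available as shell commands
(`methylink simulate|score-global|count-hyper-cgi|pmd|aneuploidy|regress|
enrich|ssgsea|partial-corr|survival|run`).

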