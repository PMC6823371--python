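# autozyg

Inbreeding-depression analysis from runs of homozygosity, with a
gene-dropping simulator providing exact ground truth.

## The problem

Offspring of related parents carry long genomic segments that are
homozygous because both copies descend from a single ancestral
haplotype (*autozygosity*). On SNP-array data these segments are visible
as **runs of homozygosity (ROH)**, and the fraction of the autosomal
genome inside ROH longer than 1.5 Mb — the genomic inbreeding
coefficient *F*<sub>ROH</sub> — predicts the directional decline of
fitness-related traits known as inbreeding depression. Estimating that
decline credibly is hard: consanguinity is socially patterned, so naive
regressions of traits on *F*<sub>ROH</sub> absorb environmental
confounding, and per-cohort effects must be pooled across populations
with very different demographic histories.

`autozyg` implements the full analysis chain used by large
multi-cohort consanguinity studies, at desk scale and fully testable:

1. **Genotypes** — PLINK ped/map and bed/bim/fam I/O, array QC
   (SNPs with >3% missingness or MAF <5% removed, then samples with >3%
   missingness).
2. **Simulation** — labelled founder haplotypes gene-dropped through
   second-cousin, first-cousin, avuncular, full-sib and parent–offspring
   unions with Poisson recombination, so every offspring has exact IBD
   truth segments; traits generated under directional dominance (rare
   recessive deleterious loci), with covariates, sex-specific effects
   and an optional family-level confounder correlated with parental
   relatedness.
3. **ROH calling** — the classic 50-SNP sliding-window scan
   (window-het 1, window-missing 5, min 50 SNPs / 1500 kb, max gap
   1000 kb, max density 50 kb/SNP, 5% hit threshold).
4. **Inbreeding estimators** — *F*<sub>ROH</sub> (with its exact split
   into <5 Mb and ≥5 Mb components), excess SNP homozygosity
   *F*<sub>SNP</sub> = (O(HOM) − E(HOM)) / (N − E(HOM)),
   *F*<sub>SNP</sub> outside ROH, the GRM-diagonal estimator
   *F*<sub>GRM</sub>, and MAF-stratified excess homozygosity.
5. **Effect models** — covariate residualization (optionally mixed-model
   residuals via REML/BLUP on a GRM), univariate / partitioned /
   bivariate regressions, logistic and scaled-linear ln(OR) estimates
   for binary traits, fixed *F*<sub>ROH</sub> bins, and the
   within-sibling design: slopes fitted on deviations from full-sib
   family means, where variation in *F*<sub>ROH</sub> arises from
   Mendelian segregation alone and is therefore immune to every
   between-family confounder. Full siblings are found from genotypes by
   method-of-moments kinship (>0.175) and IBS0 (>0.001).
6. **Meta-analysis** — fixed-effect inverse-variance pooling of
   per-cohort slopes and bin means, and parametric-bootstrap medians and
   95% CIs for unitless ratios of effect estimates across traits.

Effects are conventionally quoted as β<sub>0.0625</sub> = 0.0625 β, the
expected change in the offspring of first cousins, whose expected
autozygosity is 6.25%.

## Worked example

Simulate eight consanguineous cohorts (180 offspring each, mixed
unrelated / first-cousin / avuncular / full-sib unions on a downscaled
20 × 30 Mb genome) with a trait whose inbreeding load is
B = Σ |d| q (1 − q) = 3.80 trait units, then run the chain and pool:

```python
import numpy as np
from autozyg import (call_roh, fit_univariate, inbreeding_profile, ivw_meta,
                     qc_filter, residualize, roh_sample_summary, simulate_cohort)
from autozyg.pipeline import cohort_config_from_dict

cohort = {
    "design": {"unrelated": 15, "first_cousin": 20, "avuncular": 15,
               "full_sib": 10},
    "offspring_per_family": 3,
    "n_chrom": 20, "chrom_length_bp": 30_000_000, "snps_per_chrom": 1000,
    "traits": [{"name": "height", "recessive": [[0.05, -4.0]] * 20,
                "residual_sd": 1.0}],
}
ests = []
for seed in range(1, 9):
    bundle = simulate_cohort(cohort_config_from_dict(dict(cohort)), seed=seed)
    g, _ = qc_filter(bundle.genotypes)
    segments = call_roh(g)
    summary = roh_sample_summary(segments, g.samples.sample_id)
    t = inbreeding_profile(g, segments, summary, genome_size_bp=20 * 30e6).table
    pheno = bundle.phenotypes.set_index("sample_id").loc[t["sample_id"]]
    eps = residualize(pheno["height"].to_numpy(), np.ones((len(t), 1)))
    ests.append(fit_univariate(eps, t["f_roh"], "uni_froh", trait="height",
                               cohort=f"cohort{seed}"))
pooled = ivw_meta(ests)
print(f"pooled beta_FROH = {pooled.beta:+.2f} (se {pooled.se:.2f}, "
      f"p = {pooled.p:.2e})")
```

Output:

```
cohort1: beta_FROH =  -7.37 (se 1.59), n = 180
cohort2: beta_FROH =  -3.20 (se 1.50), n = 180
...
cohort8: beta_FROH =  -1.19 (se 1.31), n = 180
pooled over 8 cohorts: beta_FROH = -4.11 (se 0.50, p = 1.28e-16)
```

Individual cohorts are noisy (per-cohort standard errors ~1.3–1.6), but
the inverse-variance pooled slope, −4.11 ± 0.50, recovers the configured
load of −3.80 within its confidence interval: the trait loses about a
quarter of a unit (β<sub>0.0625</sub> = −0.26) in the offspring of first
cousins under this architecture.

## Documentation

`docs/methods.md` describes the models, the simulator's assumptions,
default parameters and known limitations.
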