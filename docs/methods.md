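# Methods

## Scope and model

`autozyg` estimates inbreeding depression — the directional change of a
trait with the autozygous fraction of the genome — from SNP-array
genotypes, and validates every stage against simulated cohorts whose
autozygosity is known exactly. The generative model it assumes (and
simulates) is directional dominance: many rare, deleterious, recessive
loci whose homozygous state is created chiefly by identity-by-descent.
Under this model a trait with recessive loci (frequency *q*<sub>l</sub>,
homozygous deviation *d*<sub>l</sub> < 0) declines linearly in the
autozygous fraction *F* with slope −B, where

B = Σ<sub>l</sub> |d<sub>l</sub>| q<sub>l</sub> (1 − q<sub>l</sub>),

because the probability of being homozygous for the deleterious allele
at locus *l* is q<sub>l</sub>² + F q<sub>l</sub>(1 − q<sub>l</sub>).
This closed form is exposed as `TraitModel.load` and is the reference
value for every recovery test.

## Simulation (gene dropping)

Founder haplotypes are drawn independently per site from a configurable
frequency spectrum and carry a persistent ancestral label. Gametes are
formed with Poisson crossovers, no interference, on a uniform genetic
map (default 1 cM/Mb); offspring of the five supported consanguineous
unions (second-cousin, first-cousin, avuncular, full-sib,
parent–offspring — expected F = 1/64, 1/16, 1/8, 1/4, 1/4) are bred
through explicit mini-pedigrees with fresh founders per family.
Autozygous truth segments are the intervals where an offspring's two
haplotype mosaics carry the same founder label — computed exactly from
the breakpoints, not from genotypes.

Default genome: 22-like downscaled layout of 20 chromosomes × 50 Mb for
pedigree expectations, 20 × 30 Mb for cohort-level work. The Eq-for-F
denominator (3 Gb for real human data) is a parameter everywhere, set to
the simulated genome size in tests. Causal loci are gene-dropped with the
array SNPs but withheld from the emitted genotype matrix by default,
mimicking untyped rare variation: the only path from genotype to trait
visible to the analyst runs through ROH, as the dominance model implies.
Sibships share both parents; the optional confounder is constant within
a family and correlated (configurable ρ) with the expected consanguinity
of the parents' union — the structure the within-sibling design is meant
to defeat.

What the simulator does **not** model: linkage disequilibrium beyond
segment sharing, coalescent population history, crossover interference,
sex chromosomes, genotyping error. Consequently, passing tests show the
estimators and designs are correct under the stated model; they do not
certify behaviour under array artefacts or strong LD.

## ROH calling

The caller reimplements the windowed scan standard for array data:
50-SNP windows slide one SNP at a time (only windows fully inside a
chromosome count); a window is homozygous if it has ≤1 heterozygous and
≤5 missing calls; a SNP is eligible when ≥5% of the windows containing
it are homozygous; maximal eligible runs are split at inter-SNP gaps
>1000 kb, trimmed to homozygous non-missing endpoints, and kept if they
have ≥50 SNPs, span ≥1500 kb (inclusive), and average ≤50 kb/SNP. SNPs
below 5% MAF are removed before scanning; no LD pruning is applied.
Segment length is the bp span between first and last SNP (no +1), which
matters for borderline 1500 kb calls. The 5% window-hit threshold is not
part of the usual seven published parameters; the reference tool's
default is adopted and exposed. Edge semantics (trimming, gap-splitting
order) are pinned by a brute-force oracle in the test suite, which is
authoritative where reference-tool behaviour is undocumented.

## Estimators

Per sample: *F*<sub>ROH</sub> = Σ segment lengths / genome size, split
exactly (bitwise, by construction) into <5 Mb and ≥5 Mb classes
(boundary segments count as long); *F*<sub>SNP</sub> =
(O(HOM) − E(HOM)) / (N − E(HOM)) with E(HOM) = Σ (1 − 2pq) over the
sample's non-missing SNPs; *F*<sub>SNP outside ROH</sub> uses the same
statistic with the observed homozygote count reduced by homozygotes
inside ROH and the expectation prorated by the SNP fraction outside ROH
(≈ *F*<sub>SNP</sub> − *F*<sub>ROH</sub>, asserted within 0.05 on
simulated cohorts); *F*<sub>GRM</sub> is the GRM-diagonal
(x² − (1+2p)x + 2p²) / (2p(1−p)) averaged over polymorphic SNPs.
Frequencies are in-sample and include the index individual, which
biases expectations by O(1/n) in very small cohorts; all estimators are
invariant to which allele is counted. Undefined cases (all informative
SNPs monomorphic, whole genome inside ROH) yield NaN and are excluded
downstream rather than silently zeroed.

## Effect models

Traits are first residualized on fixed covariates by OLS. For
family-structured cohorts, mixed-model residuals y − Xb̂ − û are
available: the polygenic variance ratio is estimated by REML on the
eigenrotated GRM (each likelihood evaluation is O(n) after one
eigendecomposition) and û is the BLUP at the optimum; a flat or
boundary likelihood falls back to λ = 0, i.e. plain OLS, and an optional
calibration factor on the residuals is exposed because downstream slope
scales are sensitive to BLUP shrinkage. Binary traits use either a full
logistic model (f and covariates fitted simultaneously; no mixed model)
or the scaled-linear route — y divided by its variance, then analysed
as a quantitative trait — which is asymptotically unbiased on the
ln(odds-ratio) scale; both are reported and tested for agreement.

Bin summaries use the canonical bounds
{0, 0.002, 0.0041, 0.0067, 0.0108, 0.0186, 0.0333, 0.06, 0.10, 0.18,
1.0}, left-closed/right-open with the last bin closed, so F = 0 is
binnable; residual means are referenced to the F<sub>ROH</sub> = 0
intercept of the univariate fit so cohorts with different mean F pool
coherently.

Full siblings are detected from genotypes alone: robust
method-of-moments kinship (heterozygote concordance) with IBS0
(opposite-homozygote fraction), thresholds kinship >0.175 and IBS0
>0.001; the IBS0 floor excludes parent–offspring pairs and MZ-like
pairs are deliberately retained (they add trait replicates to the
within-family variance estimate). The within-sibling slope regresses
residual deviations from family means on F<sub>ROH</sub> deviations,
through the origin (deviations sum to zero per family by construction,
so an intercept is redundant; one is available behind a flag). Naive
standard errors lose one degree of freedom per family; family-clustered
standard errors are reported alongside because the appropriate choice
depends on family-size imbalance.

## Meta-analysis

Strictly fixed-effect inverse-variance: pooled β = Σwβ/Σw,
se = 1/√Σw, w = 1/se²; Cochran's Q is reported descriptively only.
Ratios of effect estimates across traits (e.g. within-sib : population)
are summarised by a parametric bootstrap — each estimate redrawn from
N(β̂, se²) — because only summary statistics reach the meta stage;
normality of the ratio itself is not assumed. Both an unweighted
(median across traits) and a precision-weighted pooling are reported,
since the weighting convention is a genuine free choice. Default
10,000 replicates, seed mandatory.

## Numerical and design choices

- Missing genotype calls are a distinct sentinel (−1), never conflated
  with homozygous-reference.
- QC order is fixed: SNP filters (missingness, then-MAF jointly) before
  sample filters, and reported, because order changes marginal
  missingness. A SNP at exactly 5% MAF is retained (removal is strict).
- Coordinates are 1-based inclusive bp throughout, matching PLINK map
  conventions; BED-style exports document the half-open conversion.
- One master seed per simulated cohort, with per-stage derived streams
  (map, founders, drop, traits, missingness), makes bundles bit
  reproducible.
- Test problem sizes (20 × 30–50 Mb genomes, 120–250 samples, 50
  recovery replicates) were chosen so pedigree expectations resolve
  within 3 Monte-Carlo standard errors and pooled recovery tests have
  sub-unit standard errors, while the whole suite stays fast.

## Known limitations

- The caller's edge behaviour is defined by this package's oracle, not
  by any external tool; rare borderline segments may differ from other
  implementations.
- In-sample allele frequencies make F\_SNP / F\_GRM slightly biased in
  tiny cohorts; no external reference panel is supported.
- The simulator's uniform recombination map keeps expectations analytic
  but understates the variance of autozygosity relative to a real map.
- Logistic models have no family-structure correction; separation is
  reported as an error rather than penalised.
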