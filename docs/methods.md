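# Methods

This note documents the statistical models, the synthetic-data
generators, the numerical choices, and the limitations of `dyadgwas`.

## Study design the package assumes

Two linked designs: (1) a case-control sample genotyped at biallelic
SNPs, with case status the pregnancy outcome (e.g. placental
abruption) and the genotyped tissue either maternal or placental; and
(2) mother–child duos — the mother's genotype plus the child's
(placental) genotype at the same variant — classified by whether the
pregnancy was affected. Fathers are not genotyped; all inference about
parental origin comes from the cells where origin is forced by
Mendelian transmission.

## Quality control

Filters run in the order samples → SNPs → HWE:

1. samples with missing fraction > `max_sample_missing` (default 0.10);
2. SNPs with missing fraction > `max_snp_missing` (0.10) **or** MAF <
   `min_maf` (0.01), reported as a single combined tally;
3. SNPs with exact-HWE p < `hwe_alpha` among the remaining controls.

The HWE test enumerates every heterozygote count compatible with the
observed allele counts and sums the probabilities of configurations no
more probable than the observed one (two-sided exact convention);
log-gamma arithmetic keeps it stable at any sample size. The test runs
on controls only because HWE violation among controls flags genotyping
artifacts, whereas cases may deviate through genuine association.
`hwe_alpha` defaults to 1e-4, a common genome-wide choice; it is a
config knob because no single value is canonical. MAF is computed on
all retained samples for filtering but reported among controls in
outputs. The QC report is additive by construction (retained = input −
removals), and the filters are idempotent.

## Association scan

Per SNP: additive minor-allele dosage, intercept, optional covariates,
and the top principal components (default 4) in a logistic model fit by
iteratively reweighted least squares (Newton steps; converged when the
largest coefficient change drops below 1e-8, 50-iteration cap). Wald
standard errors come from the observed information; perfect separation
is flagged with an infinite-OR sentinel rather than raised. Samples
missing that SNP's genotype are dropped pairwise — standard GWAS
practice, avoiding a global imputation step in the scan. Multiple
testing uses Benjamini–Hochberg step-up q-values; the genomic inflation
factor is λ = median(χ²₁)/0.454936. PCA standardizes dosages by
√(2p̂(1−p̂)) after per-SNP mean imputation and takes the top left
singular vectors (scaled by the singular values) as scores;
zero-variance SNPs are skipped. Baseline case/control characteristic
comparisons use the Welch (unequal-variance) t-test for continuous
summaries and Pearson chi-square without continuity correction for
count tables.

## Penalized selection

One coordinate-descent engine serves all penalties. The logistic loss
is majorized by the quadratic bound with curvature 1/4 (the logistic
Hessian bound), giving working residuals on which coordinate descent
runs; the outer majorization loop repeats until the coefficient vector
changes by less than `tol` (1e-6). Dosage columns are standardized
internally (reported coefficients are per minor allele on the original
scale); the intercept, covariates and PCs are never penalized — they
are adjustment terms, not candidates.

- **Lasso**: soft-threshold updates; the path maximum λ_max =
  max_j |x_jᵀ(y − ȳ)|/n (KKT at the null model).
- **MCP / cMCP**: local linear approximation — each outer iteration
  re-weights a lasso by MCP′(|β_j|; λ, γ) = max(0, λ − |β_j|/γ), with
  γ default 3. The composite (bi-level) penalty applies an outer MCP to
  each gene's sum of inner MCP-penalized |coefficients|; its outer
  derivative is normalized to 1 at zero (so λ_max matches the lasso's)
  and fades linearly, vanishing exactly when every member coefficient
  saturates. A one-SNP gene needs no within-gene selection, so
  singleton groups bypass the outer layer and reduce structurally to
  plain MCP.
- **Group lasso**: block soft-thresholding with per-group penalty
  λ√K_g.

The penalty is chosen by K-fold cross-validation (default 20 folds, 100
log-spaced penalties down to 0.01·λ_max) minimizing mean binomial
deviance on the held-out fold; the fold assignment is a deterministic
function of the seed. Deviance is used because the CV loss is otherwise
unspecified in this design; misclassification error gives coarser,
tie-prone curves at these sample sizes. Missing dosages are mode-imputed
per SNP before penalized fits (`mode_impute`), a deliberately simple,
deterministic stand-in for haplotype-based imputation, which is out of
scope. LD expansion reports, for each selected SNP, every
same-chromosome SNP within ±500 kb whose squared Pearson dosage
correlation (pairwise-complete samples, composite-LD convention) is at
least 0.8; proxies annotate the report and never enter the model. The
joint refit is a single unpenalized logistic model of all selected SNPs
plus adjustments; a rank-deficient design falls back to a small-ridge
fit with every record flagged.

## Weighted genetic risk score

Per replicate: a stratified random partition into 10 folds (case:control
ratio preserved — unstratified folds can go single-class at a few
hundred samples); per fold, a multivariable logistic fit of status on
the fixed SNP set plus covariates in the 9 training folds. The risk
allele at each SNP is the allele with a positive training coefficient
and its weight the absolute training log-OR, making every weight
non-negative so "number of risk alleles × effect size" is well defined;
this is equivalent to signed-weight scoring up to an additive constant
and therefore leaves ranks, quartiles and AUC unchanged. Held-out
samples are scored only by the model that excluded them. Quartile
cut-points come from the replicate's pooled control scores (every
control appears exactly once per replicate, keeping the groups filled);
cut-points are order statistics (lower-quantile convention, ties fall
downward), so quartile assignment is invariant under any strictly
increasing transform of the scores. A logistic model of status on
quartile indicators plus covariates gives ORs vs the lowest quartile
and a 3-df likelihood-ratio global test; AUC is the Mann–Whitney
statistic with ties counted ½. Over replicates (default 1000), point
estimates are exponentiated means of replicate log-ORs and intervals
are 2.5–97.5 percentiles — the most direct summary of
"estimates over replicates". The replicate-percentile interval
captures partition variability only, not sampling variability of the
cohort; it should not be read as a confidence interval for the
population quartile OR.

## Dyad multinomial models

Cells and population probabilities (p = 1 − q):

| cell (m, c) | population mass | origin of child's risk allele |
|---|---|---|
| (0,0) | p³ | — |
| (0,1) | p²q | paternal (forced) |
| (1,0) | p²q | — |
| (1,1) | p²q + pq² | maternal / paternal (mixed) |
| (1,2) | pq² | both |
| (2,1) | pq² | maternal (forced) |
| (2,2) | q³ | both |

Case cells re-weight each origin-resolved configuration by
μ(m, c, origin) = S_m R_c Im^[c=1 ∧ maternal] γ₀₁^[m=0,c=1]
γ₂₁^[m=2,c=1] and renormalize; control cells use the unconditioned
population probabilities (rare-disease approximation, with no
correction for conditioning controls on non-disease). The imprinting
multiplier applies only to heterozygous children whose risk allele is
maternally derived: a homozygous child's risk is already captured by
R₂, and restricting Im to heterozygotes is the parametrization in
which parental origin is unambiguous wherever Im acts.

Fitting maximizes the multinomial log-likelihood over (logit q, log of
each free multiplier) with L-BFGS-B from five deterministic perturbed
starts around moment-style initials (q from pooled allele counts,
multipliers at 1); box bounds (|logit q| ≤ 12, |log multiplier| ≤ 8)
keep every cell probability strictly positive so the objective stays
finite. q is estimated jointly from case and control duos (controls
carry most of the information under the model). Parameter counts:
Null 1, F and M 3, M+F 5, M+F+Im 6, I 7 (q included); BIC =
−2ℓ + k ln(n dyads). The model-comparison table has a fixed seven-row
nested layout and the smallest BIC among {Null, F, M, M+F, I} selects
the model. The imprinting scan reports the 1-df asymptotic χ² LRT of
M+F+Im against M+F per variant, flagging p < 0.05; monomorphic
variants are skipped with a flag.

## Synthetic data

The generators emulate exactly the structure the analyses assume:

- **Genotypes**: haplotypes from a stationary first-order Markov chain
  with per-SNP allele frequency uniform on `maf_range` and adjacent
  correlation `ld_rho` — the simplest mechanism giving a tunable,
  monotone r² decay, which is all the LD-expansion rule needs; genotype
  = sum of two haplotypes, so HWE holds by construction.
- **Disease**: logit P = logit(baseline_risk) + Σ ln(OR)·dosage;
  case/control quotas filled by rejection sampling, which draws from
  the exact conditional distributions. Defaults mirror the study scale:
  280/244 cases/controls, 222/198 dyads, ~1% baseline risk.
- **Stratification**: a two-subpopulation mixture with
  Balding–Nichols-style Beta-distributed per-SNP frequency divergence —
  enough to make PC adjustment testable; the true label is kept as a
  covariate.
- **Dyads**: mother ~ HWE(q), maternal transmitted allele uniform over
  her two, paternal allele ~ Bernoulli(q), affection ~
  baseline_risk × μ; conditional sampling by rejection, with a
  per-dyad truth log of dosages and parental origin.
  `sample_dyad_counts` draws the 7-cell counts directly from the
  analytic conditional probabilities — the identical distribution at a
  fraction of the cost — for many-replicate calibration studies.
- **Missingness**: independent entry-level masking at combined
  per-sample/per-SNP rates.

Everything is reproducible from one integer seed; all sub-streams
derive from it deterministically.

What the generators do **not** emulate — and hence what passing tests
cannot certify about real data: realistic recombination and LD-block
structure, allele-frequency spectra from demography, genotyping batch
effects or non-random missingness, imputation error, X-chromosome
inheritance, and relatedness between samples. Tests certify the
*procedures* (calibration, recovery, selection behavior) under the
stated model, not field performance on any particular cohort.

## Numerical choices and degenerate inputs

- Minor allele defined among controls; ties broken lexicographically
  for determinism. Monomorphic variants get a placeholder minor allele
  and zero dosage everywhere.
- Mendelian-incompatible duos ((0,2), (2,0)) are excluded per variant
  and counted in an exclusion report — exclusion-with-report is a
  design choice, since no canonical handling exists for this design.
- Dyad fits require ≥ 20 dyads; the LRT errors on a negative statistic
  beyond −1e-6 (an optimization failure) and clips smaller negatives
  to 0.
- The lasso/cMCP engine drops non-converged penalty values from the CV
  curve with a warning rather than failing the path.
- All-missing dosage vectors, single-class AUC inputs, empty selections
  and zero-variance two-group tests raise or flag explicitly — never
  silent NaNs.

## Known limitations

- The cMCP outer-penalty normalization is this package's own
  (documented above); other implementations scale the outer penalty
  differently, so selected sets can differ near the threshold even at
  identical λ.
- CV-min penalty selection tends to over-select at small n; the
  chosen-penalty curve is returned so a user can apply a stricter rule.
- The dyad BIC convention (k counts q; n = dyads) is self-consistent
  but not the only possible bookkeeping; BIC values are comparable
  within this package only.
- Asymptotic χ² p-values are used for the imprinting LRT; exact
  small-sample calibration is not guaranteed. The acceptance suite
  verifies the type-I error lies in [0.03, 0.07] at nominal 0.05 with
  500 dyads per replicate.
- Wald CIs in the scan are symmetric on the log scale and degrade at
  very low MAF or near-separation; such records are flagged.
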