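# Methods

This note documents the statistical models `pathgrs` implements, the
defaults it ships, the numerical choices that are not forced by the
mathematics, and the limits of what its synthetic cohorts demonstrate.

## The analysis model

The pipeline targets a candidate-gene design: *n* ≈ 580 young adults, a
panel of 19 genotyped SNPs in three lipid-metabolism pathways, and two
phenotypes — triglycerides (TG) and HDL-cholesterol (HDL-C), both mg/dL.

Phenotypes are screened with Shapiro–Wilk (α = 0.05); non-normal variables
are analysed on the natural-log scale and results back-transformed
(geometric means) for interpretation. In practice TG is log-transformed
and HDL-C is not.

Per-SNP association is ordinary least squares with additive dosage coding,

    E[y] = β₀ + β_g·g + β_age·age + β_sex·sex [+ β_bmi·bmi] [+ γ'·PCs]

with complete-case analysis per model. Two parallel fits serve different
outputs: the dosage fit supplies β (the weight for weighted scores), Wald
p, and partial R²; a genotype-as-category fit supplies least-squares class
means at covariate means, with Tukey–Kramer (studentized-range) adjustment
for the pairwise class comparisons within that one model. No across-SNP
multiplicity adjustment is applied — each SNP is reported at its nominal p.

Partial R² ("% variability explained") is Type-III: (SSE_reduced −
SSE_full)/SS_total, algebraically equal to the nested-model ΔR². The test
suite verifies this identity to 1e-10 against independently computed
nested fits on every model class.

The risk allele is assigned per phenotype from the fitted direction:
for TG the allele increasing the adjusted mean, for HDL-C the allele
decreasing it. A zero β is flagged ambiguous and the minor allele is
reported with a warning. Because the assignment is in-sample, a variant's
risk allele can differ between phenotypes and, at small |β|/SE, between
random seeds; this is a property of the in-sample procedure, not a defect.

## Quality control and LD

- Hardy–Weinberg: 1-df Pearson χ² against expected counts at the sample
  allele frequency, no continuity correction; exclusion at p < 0.05.
  The α is a convention choice (the global significance level); it is
  configurable. Monomorphic SNPs are not testable and are excluded with
  their own reason code.
- Call rate < 0.9 excludes a SNP (configurable).
- LD is computed on unphased dosages, within chromosome: r² is the
  composite estimator (squared Pearson correlation of dosage vectors) and
  D′ comes from EM haplotype frequencies (tolerance 1e-8, ≤1000
  iterations; only the double-heterozygote cell is ambiguous).
  Non-convergence is reported, not raised.
- Pruning: connected components of the high-LD graph collapse to the
  member with the greatest phenotype variance explained (partial R² in the
  age+sex model). **High LD requires both D′ ≥ 0.8 and r² ≥ 0.1.** The r²
  floor is deliberate: a rare variant riding on a common haplotype shows
  D′ = 1 with negligible allelic correlation (the panel's ABCA1 pair,
  r² ≈ 0.04, is the motivating case) and carries independent information;
  collapsing on D′ alone would wrongly discard it. Ties break to the
  larger MAF, then the lexicographically smaller rs id.
- The ABCA1 pair is instead handled by a per-phenotype membership map in
  the panel: rs4149310 serves the TG score, rs9282541 the HDL-C score.

## Scores

Additive scores sum risk-allele counts over members; weighted scores sum
β̂_j·g_j with β̂ from the per-SNP age+sex model, re-expressed per
risk-allele copy. Under that convention TG weights are typically positive
and HDL-C weights negative (adverse = lower HDL-C), so raw weighted HDL-C
scores sum negative. Individuals missing any member genotype are excluded
from that score (complete-case; expected-dosage imputation is available
but off by default). The median split assigns "high" to scores strictly
above the sample median, computed on the analysed sample per score.

Weighted scores built from in-sample β̂ overfit: even null members
contribute E[ΔR²] ≈ k/n. The key-SNP-removal sensitivity analysis is
therefore run on additive scores in the tests, and weighted-score results
should be read as descriptive variance decomposition, not out-of-sample
prediction. External weights would remove this bias but are unavailable
for the population this design emulates.

## Ancestry

AIMs dosages are centred by 2p̂ and scaled by √(2p̂(1−p̂))
(Patterson-style) with mean imputation of missing genotypes, then
decomposed by SVD. The first two PCs (configurable) are the admixture
covariates; component signs are fixed by making the largest-magnitude
loading positive, so results are stable under AIM reordering. Monomorphic
AIMs are dropped with a warning.

## The synthetic cohort generator

The generator is the package's substitute for the non-public study data;
its defaults are the emulated study conditions and are not tuned per test:

- n = 580; sex 1 = male with P = 265/580; age ~ Normal(18.9, 0.9) truncated
  to [18, 25]; BMI ~ Normal(23.6, 4.0) truncated to [12, 60]. The
  distribution families are modelling choices matching the cohort's
  reported means and dispersions.
- Genotypes: two Bernoulli(p) draws per SNP at the panel's cohort allele
  frequencies — Hardy–Weinberg by construction. Two haplotype blocks give
  the LD structure the pruning stage expects: the ANGPTL4 trio and the
  CD36 pair, both at D′ = 1 with r² well above the prune floor. The
  flagged CD36 variant (rs3173798) is drawn with inbreeding-style
  coefficient F = 0.35, so the Hardy–Weinberg screen rejects it from data
  (χ² ≈ nF² ≈ 70 at n = 580).
- TG: log TG = intercept + Σβ_j g_j + 0.010·(age−18.9) + 0.04·sex +
  0.015·(BMI−23.6) + N(0, 0.42²). The residual SD 0.42 reproduces a cohort
  TG SD near 50 mg/dL at mean ≈ 108; per-SNP log effects of 0.02–0.05 give
  single-SNP variance fractions of order 10⁻²–10⁻³. These magnitudes are
  approximations chosen from the cohort's summary moments; no per-SNP
  effect sizes are published for this population.
- HDL-C: raw scale, sex effect −4 mg/dL, residual SD 11; one dominant
  protective-variant effect (rs9282541, −3.5 mg/dL per T allele ≈ SNP R²
  0.016) and small effects elsewhere; the LPL variant raises HDL-C so its
  HDL risk allele is the partner allele, exercising the per-phenotype
  risk-allele logic.
- Admixture: q ~ Beta(6, 4) (mean 0.6, SD ≈ 0.15); 64 AIMs with ancestral
  frequency pair (0.8, 0.2) by default. AIM genotypes are two Bernoulli
  draws at q·p₁ + (1−q)·p₂. Confounding scenarios additionally let score
  SNP frequencies and the phenotype depend on q; the packaged scenario
  uses (0.9, 0.1) AIMs so the PCs measure ancestry well (|corr(PC1, q)| ≈
  0.94), score-SNP differential (0.7, 0.3), and an 11 mg/dL (≈1 SD)
  ancestry effect on HDL-C — strong enough that the unadjusted type-I
  error visibly inflates (~0.24) while two PCs restore ~0.05.
- Missingness is completely at random at rate 0.01.
- One seed drives everything through named SeedSequence-spawned streams
  (genotypes, missingness, aims, covariates, tg, hdl, admixture), so
  outputs are byte-identical across runs and changing one stage's draws
  cannot perturb another's.

What the generator does **not** emulate: realistic human LD maps beyond
the two explicit blocks, >2 ancestral populations, relatedness/family
structure, informative missingness, genotype-calling error, diet and
lifestyle covariates, and gene–sex or gene–gene effects unless configured.
Passing tests therefore certify the statistical machinery under the
assumed generative model — they do not certify that real cohort effects of
these sizes exist.

## Numerical and procedural choices

- OLS via statsmodels; Wald 95% CIs (normal approximation is adequate at
  n ≈ 580). Singular designs (monomorphic SNP, collinear interaction
  pair) are flagged and skipped rather than fitted.
- Tukey–Kramer p-values use the studentized-range survival function with
  the categorical model's residual df; k = number of observed genotype
  classes.
- The interaction scan fits every within- and across-pathway pair of
  retained SNPs and flags pairs with dosage r² ≥ 0.99 as collinear.
- Sex-stratified models drop sex from the covariates and require n ≥ 30
  per stratum; no formal gene–sex interaction test is attempted (the
  emulated design is underpowered for it).
- TG guideline categories: <90 Optimal; [90, 130) Early metabolic risk;
  [130, 150) Borderline metabolic risk; ≥150 Clinical
  hypertriglyceridemia. Low-HDL and high-TG flags follow ATP-III-style
  cutoffs (<40/<50 mg/dL by sex; ≥150 mg/dL).
- Problem sizes in the test suite (replicate counts of 200–1000 at
  n = 580, LD checks at n = 5000) are chosen so Monte-Carlo error is small
  relative to the asserted tolerances while the whole suite runs in about
  a minute.

## Known limitations

In-sample weights overfit (see above); the pipeline reports but does not
cross-validate them. The EM D′ estimator assumes Hardy–Weinberg within
each locus when resolving double heterozygotes. The VCF reader handles
biallelic records with GT only. X-chromosome dosage, imputation, and
multi-allelic variants are out of scope.
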