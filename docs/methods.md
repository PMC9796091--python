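# Methods

## Model

The analysis unit is the genotyped parent–offspring trio, with one
phenotype measurement on the offspring. Writing y for the N-vector of
offspring phenotypes,

    y = X β + g_o + g_m + g_p + ε,

with X = [1, sex]. The genetic effects are multivariate normal with
covariance across trios given by genomic relatedness: if A is the
SNP-based GRM over all trio members, the model covariance of y is

    V(θ) = σ²_o A_oo + σ²_m A_mm + σ²_p A_pp
         + σ_om (A_om + A_omᵀ) + σ_op (A_op + A_opᵀ)
         + σ_mp (A_mp + A_mpᵀ) + σ²_ε I,

where A_rs is the (role r, role s) block of A restricted to the N trios.
V is linear in the seven raw parameters; every specification below is a
linear constraint on them, so V stays linear in each specification's
parameter vector — a property tested by finite differences and relied
on for gradients and information matrices.

Expected block structure under random mating: diag(A_om) = diag(A_op) =
1/2 and diag(A_mp) = 0. Hence each direct–indirect covariance
contributes exactly its own value to the phenotypic variance (2 × 1/2),
and the mate covariance σ_mp contributes nothing:

    Var(y | sex) = σ²_o + σ²_m + σ²_p + σ_om + σ_op + σ²_ε.

### Nested specifications

- differential (7 df): all parameters free.
- combined (4 df): maternal and paternal effects equal and perfectly
  correlated, equally correlated with the direct effect
  (σ²_m = σ²_p = σ_mp = σ_par, σ_om = σ_op = σ_o,par).
- no_parental (2 df): direct effects only — ordinary GRM heritability.
- null (1 df): residual only.

## Estimation

Full maximum likelihood, not REML: the AIC convention used for model
comparison, −2ll + 2(df + 2), counts the two fixed effects as estimated
parameters, which is the ML accounting. Fixed effects are profiled out
of every likelihood evaluation by generalized least squares, so the
optimization runs over variance parameters only. Each evaluation
factors V once (Cholesky) and reuses the factor for the GLS solve, the
log-determinant and (when a gradient is needed) the explicit inverse.

Positivity and admissibility are enforced by parameterization rather
than constrained optimization: the implied genetic covariance matrix —
3×3 for differential, the 2×2 (direct, per-parent) matrix for combined —
is written as L Lᵀ with log-scale diagonal (log-Cholesky), and σ²_ε as
exp(·). Boundaries (zero variances, correlations of ±1) are reachable
in the limit; the conduct-type boundary solution r_GE → −1 is
representable. The gradient in raw parameters is analytic,

    ∂(−2ll)/∂θ_j = tr(V⁻¹ C_j) − uᵀ C_j u,  u = V⁻¹(y − X β̂),

(envelope theorem over β̂), chained through the transform Jacobian.

Optimizer: L-BFGS-B on the transformed parameters, relative −2ll
tolerance 1e-8, at most 500 iterations. Three deterministic raw-scale
starts are used — equal split, direct-heavy, residual-heavy, all scaled
to the ML residual variance of y on X. By default the starts are
screened by their initial −2ll and the full run proceeds from the best,
falling back to the others if it fails (`full_multistart=True` runs all
three to completion; a test checks both routes agree). Non-PD
covariance evaluations return a large penalized value and are counted.

### Standard errors

From the inverse expected (Fisher) information on the raw scale,
I_jk = ½ tr(V⁻¹ C_j V⁻¹ C_k). Because V is linear in θ, this is the
exact expected information (no curvature terms are dropped), it is
block-diagonal with respect to the fixed effects, and it avoids the
singular transform Jacobians that an observed-information-through-the-
parameterization route produces at boundary solutions. At boundaries
the information can still be singular; a pseudo-inverse is used and the
affected SEs should be read as approximate. Standardized estimates and
derived quantities (shares, variance explained, r_GE) carry
delta-method SEs.

### Standardization and decomposition

Estimates are standardized by the model-implied total
σ²_o + σ²_m + σ²_p + σ_om + σ_op + σ²_ε (σ_mp excluded per the variance
accounting above), so standardized components sum to one by
construction — the convention under which the published table rows sum
to ≈1. The decomposition reports the direct share, combined indirect
share σ²_m + σ²_p, covariance contribution σ_om + σ_op, residual, the
variance explained 1 − σ²_ε, and

    r_GE = (σ_om + σ_op) / sqrt(σ²_o (σ²_m + σ²_p)).

A caveat on the range of r_GE: under the combined constraint the PSD
bound is |σ_o,par| ≤ sqrt(σ²_o σ_par) per parent, which caps this
quantity at √2, not 1 (the correlation between g_o and the *sum*
g_m + g_p is what is capped at 1, and its denominator includes the
2σ_mp term that r_GE's denominator omits). The formula is kept because
it is the one whose values (−0.65, −1.00, +0.64) the published table
arithmetic reproduces; values slightly beyond ±1 can therefore occur
and should be read as boundary solutions.

### Model comparison

AIC = −2ll + 2(df + 2); sequential LRTs down the chain differential →
combined → no_parental → null with df differences 3, 2, 1 and a plain
χ² reference. Variance parameters on nested-model boundaries make the
plain χ² conservative (the true reference is a chi-bar-square mixture);
the plain version is used because it reproduces the published p-values,
and a simulation test confirms the conservative direction.

## Synthetic data generator

The generator emulates a genotyped birth-cohort trio sample:

- Parental dosages: Binomial(2, p_j), p_j ~ Uniform(maf_range), default
  maf_range (0.05, 0.5). Offspring receive one fair gamete per parent,
  so the data are Mendelian-error-free and realized parent–offspring
  relatedness is ½.
- Effects: per-SNP triples (β_o, β_m, β_p) i.i.d. trivariate normal
  with covariance genetic_cov / n_snps, applied to dosages standardized
  by the *generating* allele frequencies. This makes genetic_cov the
  variance-component target on exactly the scale the GRM estimator
  works on; the estimation side standardizes by founder-estimated
  frequencies, and that realism gap is part of the recovery tolerance.
- Phenotype: intercept + sex_effect·sex + scores + Normal(0, σ²_ε).
  Offspring sex is Bernoulli(0.5). Per-SNP effects and realized genetic
  scores are retained on the returned object for oracle tests.
- Items: a deterministic graded-threshold discretizer — each of the
  n_items carries three cut points, the cut points of all items tiling
  (0,1) evenly against the min–max-scaled latent score. Item sums are
  rank-concordant with the latent score by construction and the floor
  case maps to all-1 responses. Randomness enters only through MCAR
  masking. This is a fixture generator for the scoring pipeline, not a
  psychometric model of any rating instrument.

Not emulated: linkage disequilibrium, assortative mating, population
structure, sibling effects, genotyping batches, informant bias. Passing
tests therefore validate the estimator under its own assumptions; they
do not certify behavior under those violations.

All generators are bit-reproducible given `SimParams.seed`; independent
streams are spawned per operation from that seed.

## Quality control

Variant filters in first-fail order MAF (< 0.01) → call rate (< 0.98) →
HWE (p < .001, 1-df χ² goodness-of-fit with p estimated from counts; a
zero statistic returns p = 1). HWE is computed on founders only when
trio structure is supplied, since offspring genotypes duplicate
parental alleles. Sample filters: call rate < 0.98, then degenerate
(zero expected heterozygosity), then |F| > 0.2 with
F = 1 − observed het / Σ 2p(1−p) over the sample's called SNPs.
Dosages within 0.1 of an integer are hard calls; softer calls are
skipped and counted wherever genotype classes are needed (HWE,
heterozygosity, Mendelian logic). The Mendelian scan flags (trio, SNP)
combinations impossible under biallelic transmission — 12 of the 27
ordered hard-call triples, verified against gamete enumeration.

## Relatedness

GRM entries average standardized-genotype cross-products over SNPs,
pairwise-complete under missingness (each pair divides by its own SNP
count). Allele frequencies come from founders when a trio structure is
available. Monomorphic SNPs must be removed by QC first; the estimator
refuses p ∈ {0, 1}.

Pruning enforces a maximum allowed relatedness (default 0.10) over all
pairs of trio members except within-trio parent–offspring pairs;
within-trio mates do count. Removal is greedy by trio: repeatedly drop
the trio containing the individual with the most above-threshold edges
(ties: larger maximum edge, then lower trio index) until no violating
pair remains — the output is verified by exhaustive pair scan in tests.
This is a property-preserving substitute for pedigree-selection tools
whose exact algorithm is unspecified; only the no-violating-pairs
property is guaranteed, not set-identity with any particular tool.

## Scoring

Subscale scores are item sums over 1–4 ratings (canonical item counts
8/9/9/8 for conduct, inattention, hyperactivity, oppositional).
Individuals missing at least half of a subscale's items (exactly half
included) get a missing score; otherwise missing items are imputed with
the respondent-sample item mean — the mean over individuals for that
item, not the individual's mean over items — before summing. Scores
enter the model unstandardized; standardization happens at reporting.

## Problem sizes and runtimes

The parameter-recovery study runs 20 replicates of 2000 trios × 3000
SNPs (≈8 min on one CPU; each replicate ≈25 s, dominated by one
6000×6000 GRM and an N=2000 fit at ≈1 s per likelihood-plus-gradient
evaluation). Size-free properties (nesting monotonicity, selection
consistency, LRT calibration) are checked at 200–400 trios. The
acceptance script averages five pipeline replicates at 2000 trios ×
3000 SNPs (≈5 min); its ratio statistics (variance explained, r_GE) are
computed from the replicate-averaged components, since per-replicate
ratios are unstable when a variance estimate sits near its zero
boundary.

## Known limitations

- One phenotype at a time; no factor models across subscales, no
  sibling indirect effects, no assortative-mating or population-
  stratification corrections. Estimated "parental" effects absorb such
  confounding where present.
- ML (default) is biased downward in variance components at small N
  relative to REML; at the trio counts this design needs, the
  difference is negligible against sampling error.
- SEs at boundary solutions (zero variances, |correlation| = 1) are
  approximate; the information matrix is pseudo-inverted there.
- The item generator preserves ranks but not any real instrument's
  category thresholds, discrimination or informant effects.
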