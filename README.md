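# triovc

Direct and indirect parental genetic effects on child phenotypes,
estimated from genotyped parent–offspring trios with genomic-relatedness
variance components.

## The problem

Parents shape their children twice over: they transmit genes, and they
provide the rearing environment. For childhood externalizing symptoms
(conduct problems, inattention, hyperactivity, oppositional behavior)
the environmental half of that influence has been hard to pin down,
because any *measured* parenting variable is both incomplete and
genetically confounded. The trio design sidesteps measurement entirely:
if the relevant parenting traits are themselves heritable, the parents'
genotypes index all of them at once, so an effect of parental genotype
on the child's phenotype — beyond the child's own genotype — is evidence
of an environmentally mediated, *indirect genetic effect*.

`triovc` implements that analysis for anyone with PLINK-format trio
genotypes and an item-rated child phenotype, together with a synthetic
trio generator so the whole pipeline can be exercised, calibrated and
tested without access-restricted cohort data.

## The model

For one phenotype measurement per trio,

> y = Xβ + g_o + g_m + g_p + ε

where g_o is the child's direct genetic effect and g_m, g_p are the
maternal and paternal indirect effects. Each effect is a random vector
correlated across trios through genomic relatedness, giving

> V = σ²_o A_oo + σ²_m A_mm + σ²_p A_pp + σ_om (A_om + A_omᵀ)
>   + σ_op (A_op + A_opᵀ) + σ_mp (A_mp + A_mpᵀ) + σ²_ε I

with the six A blocks cut from one SNP-based GRM (Yang estimator) by
trio role. Because parent–offspring relatedness is ½ and mates are
unrelated, the phenotypic variance is σ²_o + σ²_m + σ²_p + σ_om + σ_op +
σ²_ε — each direct–indirect covariance contributes exactly once and
σ_mp not at all. Four nested specifications are compared by full ML:

| spec | free parameters | df |
|---|---|---|
| differential | σ²_o, σ²_m, σ²_p, σ_om, σ_op, σ_mp, σ²_ε | 7 |
| combined | σ²_o, σ_par (=σ²_m=σ²_p=σ_mp), σ_o,par (=σ_om=σ_op), σ²_ε | 4 |
| no_parental | σ²_o, σ²_ε (GRM heritability) | 2 |
| null | σ²_ε | 1 |

AIC counts the intercept and sex fixed effects as parameters
(−2ll + 2(df+2)); sequential LRTs use a plain χ² reference. A fitted
model is standardized so the sex-conditional variance is 1 and
decomposed into the direct share, combined indirect share, covariance
contribution (1−σ²_ε is "variance explained") and the
gene–environment correlation r_GE = (σ_om+σ_op)/√(σ²_o(σ²_m+σ²_p)).

## Worked example

`examples/fit_variance_components.py` simulates 2000 trios × 2500 SNPs
with σ²_o=0.25, per-parent σ_par=0.075, σ_o,par=−0.05, σ²_ε=0.70, builds
the GRM blocks and fits all four specifications:

```
       model  var_o  var_m  var_p  cov_om  cov_op  resid  neg2_loglik     aic  df  p_value  best
differential  0.234  0.097  0.036  -0.055  -0.014  0.703      5511.34 5529.34   7      NaN False
    combined  0.227  0.057  0.057  -0.028  -0.028  0.717      5512.72 5524.72   4     0.71 False
 no_parental  0.234    NaN    NaN     NaN     NaN  0.766      5516.68 5524.68   2     0.14  True
        null    NaN    NaN    NaN     NaN     NaN  1.000      5555.74 5561.74   1     0.00 False

combined-model raw estimates (+- SE) vs generating values:
    var_o: +0.214 +- 0.070   (truth +0.250)
    var_m: +0.053 +- 0.033   (truth +0.075)
   cov_om: -0.027 +- 0.041   (truth -0.050)
    resid: +0.675 +- 0.049   (truth +0.700)
```

Every generating component is inside two standard errors; −2ll is
monotone down the nesting chain; and AIC narrowly prefers the sparser
`no_parental` model in this replicate — indirect effects of this size
sit at the edge of what a few thousand trios can resolve, which is the
realistic evidential situation for this design.

The other examples cover the remaining capabilities one at a time:
`simulate_and_qc.py` (planted QC failures found, zero Mendelian errors),
`relatedness_blocks.py` (role-block means 0.50 / 0.00, hub-trio
pruning at the 0.10 threshold), `score_items.py` (item scoring with the
50%-missing rule) and `published_table_arithmetic.py` (below).

## Layout

- `triovc.simulate` — trio genotypes (Mendelian transmission), phenotypes
  with targeted variance components, ordinal item fixtures
- `triovc.qc` — variant/sample filters, HWE test, Mendelian-error scan
- `triovc.relatedness` — GRM, trio role-blocks, relatedness pruning
- `triovc.scoring` — subscale sums with the missing-data rule
- `triovc.model` — covariance construction, likelihood, ML fitting,
  standardization
- `triovc.selection` — AIC/LRT, comparison tables, decomposition, figure
- `triovc.plink` — PLINK bed/bim/fam and GCTA GRM interchange
- `triovc.published` — the published fit statistics used as worked-example
  inputs

See `docs/methods.md` for modelling assumptions, numerical choices and
known limitations.
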