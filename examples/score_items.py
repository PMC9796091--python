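"""Score ordinal items into subscale sums with the missing-data rule.

Simulates a latent externalizing phenotype for 1000 children, discretizes
it into 1-4 rated items for two subscales (8-item conduct, 9-item
inattention) with 2% missing answers, then scores the subscales: missing
items are imputed with the respondent-sample item mean unless at least
half of a subscale's items are missing, in which case the score is
dropped.
"""

import numpy as np

import triovc as tv

params = tv.SimParams(n_trios=1000, n_snps=50, resid_var=1.0, seed=4)
geno, trios = tv.simulate_trio_genotypes(params)
sim = tv.simulate_phenotypes(geno, trios, params)

conduct = tv.simulate_items(sim.table, n_items=8, missing_rate=0.02,
                            seed=10, scale="conduct")
inatt = tv.simulate_items(sim.table, n_items=9, missing_rate=0.02,
                          seed=11, scale="inattention")
items = conduct.merge(inatt, on="trio")
items["sex"] = trios.offspring_sex

scored = tv.score_subscales(items)
for name, stats in scored.attrs["completeness"].items():
    print(f"{name}: {stats['n_complete']} complete, {stats['n_imputed']} imputed, "
          f"{stats['n_excluded']} excluded "
          f"({stats['prop_missing_score']:.2%} of scores lost)")

rho = scored["conduct"].corr(sim.table["score"], method="spearman")
print(f"rank correlation of conduct score with latent phenotype: {rho:.3f}")
print(f"conduct score range: [{scored['conduct'].min():.1f}, "
      f"{scored['conduct'].max():.1f}] (bounds 8 and 32)")

# With 2% item-level missingness almost no scores are lost (the 50% rule
# bites only with extreme missingness) and the item sums preserve the
# latent ordering almost perfectly.
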