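"""Fit the four nested variance-component specifications to synthetic data.

Simulates 2000 trios x 2500 SNPs with a direct genetic variance of 0.25,
combined-parental structure (equal maternal/paternal effects, perfectly
correlated) of 0.075 per parent, a negative direct-indirect covariance
of -0.05 per parent and residual variance 0.70.  Fits all four nested
specifications, prints the comparison table and decomposes the
best-fitting model.
"""

import numpy as np

import triovc as tv

params = tv.SimParams.from_components(
    n_trios=2000, n_snps=2500,
    var_o=0.25, var_m=0.075, var_p=0.075,
    cov_om=-0.05, cov_op=-0.05, cov_mp=0.075,
    resid_var=0.70, sex_effect=0.25, intercept=1.0, seed=7,
)
geno, trios = tv.simulate_trio_genotypes(params)
sim = tv.simulate_phenotypes(geno, trios, params)

founders = np.concatenate([trios.mother, trios.father])
grm = tv.compute_grm(geno, founders=founders)
blocks = tv.trio_grm_blocks(grm, trios)

y = sim.table["score"].to_numpy()
x = np.column_stack([np.ones(trios.n_trios), trios.offspring_sex])

fits = [tv.fit_vc(name, y, x, blocks) for name in tv.NESTING_ORDER]
table = tv.model_table(fits, subscale="synthetic")
cols = ["model", "var_o", "var_m", "var_p", "cov_om", "cov_op", "resid",
        "neg2_loglik", "aic", "df", "p_value", "best"]
print(tv.render_table(table)[cols].to_string(index=False))

best_name = table.loc[table["best"], "model"].iloc[0]
print(f"\nbest model by AIC: {best_name}")

combined = next(f for f in fits if f.spec.name == "combined")
est, se, _ = combined.expanded()
print("combined-model raw estimates (+- SE) vs generating values:")
truth = {"var_o": 0.25, "var_m": 0.075, "cov_om": -0.05, "resid": 0.70}
for name in ("var_o", "var_m", "cov_om", "resid"):
    print(f"  {name:>7}: {est[name]:+.3f} +- {se[name]:.3f}   (truth {truth[name]:+.3f})")

decomp = tv.decompose_variance(tv.standardize_fit(combined))
print(f"variance explained under combined (1 - resid): {decomp.explained:.1%}")
print(f"gene-environment correlation: {decomp.ge_correlation:+.2f}")

# The -2ll column is monotone down the nesting chain and each generating
# component sits within ~2 SE of its combined-model estimate.  AIC may
# prefer the sparser no_parental model in a given replicate: with indirect
# effects this weak, thousands of trios give limited power to resolve
# them, which is exactly the evidential situation in cohort applications.
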