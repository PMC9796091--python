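"""Simulate trio genotypes and run the genotype quality-control filters.

Generates 500 parent-offspring trios at 800 SNPs, plants three bad
variants and one bad sample, and shows that the filters find exactly the
planted problems while the Mendelian scan stays clean (transmission is
Mendelian by construction).
"""

import numpy as np

import triovc as tv

params = tv.SimParams(n_trios=500, n_snps=800, maf_range=(0.05, 0.5), seed=1)
geno, trios = tv.simulate_trio_genotypes(params)

# plant failures: a monomorphic SNP, a low-call-rate SNP, an all-het SNP,
# and a sample with 10% of its calls removed
geno.dosages[:, 10] = 0.0
geno.dosages[:40, 20] = np.nan
geno.dosages[:, 30] = 1.0
rng = np.random.default_rng(0)
geno.dosages[5, rng.random(800) < 0.10] = np.nan
geno = tv.GenotypeData(geno.dosages, ids=geno.ids, snp_ids=geno.snp_ids)

variant_report = tv.variant_filters(geno, tv.QCThresholds(), trios)
sample_report = tv.sample_filters(geno)
mendel_report = tv.mendelian_error_scan(geno, trios)

print("variant exclusions:", variant_report.summary()["variant_exclusions"])
print("sample exclusions:", sample_report.summary()["sample_exclusions"])
print("Mendelian errors:", int(mendel_report.trio_mendel_errors.sum()))

# Expected: one variant per criterion (maf / call_rate / hwe), one sample
# excluded for call rate, and zero Mendelian errors.
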