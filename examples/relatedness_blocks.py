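"""Genomic relatedness in trios: role-block structure and pruning.

Builds the GRM for 800 simulated trios, extracts the six role-blocks and
checks their expected structure: parent-offspring relatedness 1/2,
unrelated mates 0.  Then plants a cross-trio relative and shows the
pruning step removing the offending trio at the 0.10 threshold.
"""

import numpy as np

import triovc as tv

params = tv.SimParams(n_trios=800, n_snps=5000, seed=2)
geno, trios = tv.simulate_trio_genotypes(params)
founders = np.concatenate([trios.mother, trios.father])
grm = tv.compute_grm(geno, founders=founders)
blocks = tv.trio_grm_blocks(grm, trios)

print(f"mean offspring-mother relatedness: {np.diag(blocks.a_om).mean():.4f}")
print(f"mean offspring-father relatedness: {np.diag(blocks.a_op).mean():.4f}")
print(f"mean mother-father relatedness:    {np.diag(blocks.a_mp).mean():+.4f}")
print(f"mean self-relatedness (offspring): {np.diag(blocks.a_oo).mean():.4f}")

# plant cross-trio relatedness: mother of trio 0 "related" to offspring of
# trios 1 and 2 at 0.25 (e.g. an aunt) -> trio 0 is the hub and is dropped
v = grm.values.copy()
hub = trios.mother[0]
for other in (trios.offspring[1], trios.offspring[2]):
    v[hub, other] = v[other, hub] = 0.25
grm_related = tv.GRM(values=v, n_snps_used=grm.n_snps_used, ids=grm.ids)

kept = tv.prune_relatedness(grm_related, trios, threshold=0.10)
print(f"trios retained after pruning: {kept.n_trios} of {trios.n_trios}")

# Expected: parent-offspring ~0.50, mates ~0.00, self ~1.00, and exactly
# one trio (the hub's) removed.  At many fewer SNPs the sampling noise of
# the GRM (sd ~ 1/sqrt(M) per entry) would push additional pairs over the
# threshold.
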