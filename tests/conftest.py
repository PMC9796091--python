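import numpy as np
import pytest

import triovc as tv

#: generating components used across tests: moderate direct effect, equal
#: parental effects perfectly correlated, negative direct-indirect covariance
GEN = dict(
    var_o=0.25, var_m=0.075, var_p=0.075,
    cov_om=-0.05, cov_op=-0.05, cov_mp=0.075,
    resid_var=0.70,
)


def make_dataset(n_trios, n_snps, seed, sex_effect=0.25, intercept=1.0, **components):
    """Simulate a trio dataset and everything the model needs from it."""
    comp = {**GEN, **components}
    params = tv.SimParams.from_components(
        n_trios, n_snps, sex_effect=sex_effect, intercept=intercept,
        seed=seed, **comp,
    )
    geno, trios = tv.simulate_trio_genotypes(params)
    sim = tv.simulate_phenotypes(geno, trios, params)
    founders = np.concatenate([trios.mother, trios.father])
    # drop SNPs monomorphic among founders (QC would remove them)
    founder_freq = geno.dosages[founders].mean(axis=0) / 2.0
    polymorphic = (founder_freq > 0) & (founder_freq < 1)
    if not polymorphic.all():
        geno = geno.select_variants(polymorphic)
    grm = tv.compute_grm(geno, founders=founders)
    blocks = tv.trio_grm_blocks(grm, trios)
    x = np.column_stack([np.ones(n_trios), trios.offspring_sex])
    return dict(
        params=params, geno=geno, trios=trios, sim=sim, grm=grm,
        blocks=blocks, X=x, y=sim.table["score"].to_numpy(),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """300 trios x 400 SNPs with the full generating covariance."""
    return make_dataset(300, 400, seed=11)


@pytest.fixture(scope="session")
def small_fits(small_dataset):
    """All four specifications fitted to the small dataset."""
    d = small_dataset
    return {
        name: tv.fit_vc(name, d["y"], d["X"], d["blocks"])
        for name in tv.NESTING_ORDER
    }
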