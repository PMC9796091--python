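"""Synthetic parent-offspring trio data with direct and indirect genetic effects.

The generator emulates the structure of a genotyped birth-cohort trio
sample: independent parental genotypes drawn from population allele
frequencies, offspring genotypes by fair Mendelian transmission, and an
offspring phenotype

    y = intercept + sex_effect * sex + g_o + g_m + g_p + eps

where ``g_o`` is the direct genetic effect of the child's own genotypes
and ``g_m``/``g_p`` the indirect effects of the mother's and father's
genotypes (mediated through the rearing environment).  Per-SNP effect
triples ``(beta_o, beta_m, beta_p)`` are i.i.d. trivariate normal with
covariance ``genetic_cov / n_snps`` and act on column-standardized
dosages, so ``genetic_cov`` is directly the target variance-component
matrix: the phenotype variance is
``sigma_o^2 + sigma_m^2 + sigma_p^2 + sigma_om + sigma_op + sigma_eps^2``
(parent-offspring relatedness of one half turns each direct-indirect
covariance into an equal variance contribution; unrelated mates make the
mother-father covariance contribute nothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ConfigurationError, GenotypeData, InputError, TrioIndex

__all__ = [
    "SimParams",
    "PhenotypeSim",
    "simulate_trio_genotypes",
    "simulate_phenotypes",
    "simulate_items",
]


def _default_genetic_cov() -> np.ndarray:
    return np.zeros((3, 3))


@dataclass
class SimParams:
    """Generative parameters for a trio simulation.

    ``genetic_cov`` is the 3x3 symmetric matrix of variance components in
    phenotype-variance units, ordered (offspring, mother, father): its
    diagonal holds sigma_o^2, sigma_m^2, sigma_p^2 and the off-diagonals
    sigma_om, sigma_op, sigma_mp.
    """

    n_trios: int
    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    genetic_cov: np.ndarray = field(default_factory=_default_genetic_cov)
    resid_var: float = 1.0
    sex_effect: float = 0.0
    intercept: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_trios < 1 or self.n_snps < 1:
            raise ConfigurationError("n_trios and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        self.genetic_cov = np.asarray(self.genetic_cov, dtype=float)
        if self.genetic_cov.shape != (3, 3):
            raise ConfigurationError("genetic_cov must be 3x3")
        if not np.allclose(self.genetic_cov, self.genetic_cov.T):
            raise ConfigurationError("genetic_cov must be symmetric")
        if (np.diag(self.genetic_cov) < 0).any():
            raise ConfigurationError("genetic_cov diagonal must be non-negative")
        if self.resid_var < 0:
            raise ConfigurationError("resid_var must be non-negative")

    @classmethod
    def from_components(
        cls,
        n_trios: int,
        n_snps: int,
        var_o: float = 0.0,
        var_m: float = 0.0,
        var_p: float = 0.0,
        cov_om: float = 0.0,
        cov_op: float = 0.0,
        cov_mp: float = 0.0,
        resid_var: float = 1.0,
        **kwargs,
    ) -> "SimParams":
        """Build parameters from the six named variance components."""
        g = np.array(
            [
                [var_o, cov_om, cov_op],
                [cov_om, var_m, cov_mp],
                [cov_op, cov_mp, var_p],
            ]
        )
        return cls(n_trios=n_trios, n_snps=n_snps, genetic_cov=g,
                   resid_var=resid_var, **kwargs)


def _rng(seed: int, stream: int) -> np.random.Generator:
    # distinct, reproducible streams per operation
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def simulate_trio_genotypes(
    params: SimParams,
    mode: str = "hard",
    dosage_noise_sd: float = 0.05,
) -> tuple[GenotypeData, TrioIndex]:
    """Draw trio genotypes: parental Binomial(2, p) calls, Mendelian offspring.

    Per SNP the population frequency ``p`` is uniform on ``maf_range``;
    each parent contributes one fair gamete to the offspring, so realized
    parent-offspring genomic relatedness is 1/2 in expectation and the
    generated data contain no Mendelian errors by construction.

    Rows are laid out in blocks: offspring ``0..N-1``, mothers
    ``N..2N-1``, fathers ``2N..3N-1``.  ``mode="dosage"`` adds Normal
    noise truncated to ``[0, 2]`` (soft calls, for QC exercises only).
    """
    if mode not in ("hard", "dosage"):
        raise ConfigurationError(f"unknown genotype mode {mode!r}")
    n, m = params.n_trios, params.n_snps
    rng = _rng(params.seed, 0)
    p = rng.uniform(params.maf_range[0], params.maf_range[1], size=m)

    mothers = rng.binomial(2, p, size=(n, m)).astype(float)
    fathers = rng.binomial(2, p, size=(n, m)).astype(float)
    # one fair gamete from each parent: Bernoulli(dosage / 2)
    gm = rng.binomial(1, mothers / 2.0)
    gf = rng.binomial(1, fathers / 2.0)
    offspring = (gm + gf).astype(float)

    dos = np.vstack([offspring, mothers, fathers])
    if mode == "dosage":
        dos = np.clip(dos + rng.normal(0.0, dosage_noise_sd, size=dos.shape), 0.0, 2.0)

    width = len(str(n - 1)) if n > 1 else 1
    ids = np.array(
        [f"{role}{i:0{width}d}" for role in ("o", "m", "f") for i in range(n)],
        dtype=object,
    )
    geno = GenotypeData(dosages=dos, ids=ids, pop_freq=p)
    sex = rng.binomial(1, 0.5, size=n)
    trios = TrioIndex(
        offspring=np.arange(n),
        mother=np.arange(n, 2 * n),
        father=np.arange(2 * n, 3 * n),
        offspring_sex=sex,
    )
    return geno, trios


def _psd_factor(g: np.ndarray, n_snps: int) -> np.ndarray:
    """Factor of genetic_cov / n_snps, rejecting non-PSD input."""
    vals, vecs = np.linalg.eigh(g)
    tol = -1e-10 * max(vals.max(), 1.0)
    if vals.min() < tol:
        raise ConfigurationError(
            f"genetic_cov is not positive semi-definite "
            f"(eigenvalue {vals.min():.6g})"
        )
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals / n_snps)


@dataclass
class PhenotypeSim:
    """Simulated phenotypes plus the generating quantities kept for oracles.

    ``table`` has one row per trio with columns ``trio``, ``sex`` and
    ``score`` (the continuous latent phenotype).  ``betas`` is the
    ``(n_snps, 3)`` matrix of per-SNP effects (offspring, mother, father)
    and ``genetic_scores`` the realized ``(n_trios, 3)`` genetic values.
    """

    table: pd.DataFrame
    betas: np.ndarray
    genetic_scores: np.ndarray
    residuals: np.ndarray


def simulate_phenotypes(
    geno: GenotypeData, trios: TrioIndex, params: SimParams
) -> PhenotypeSim:
    """Generate offspring phenotypes carrying direct and indirect effects.

    Effects act on dosages standardized with the *generating* allele
    frequencies, so the effect covariance matrix is the variance-component
    target on the same scale a genomic-relatedness analysis estimates.
    """
    trios.validate_against(geno.n_individuals)
    m = geno.n_snps
    if m != params.n_snps:
        raise ConfigurationError("params.n_snps does not match genotype data")
    p = geno.pop_freq if geno.pop_freq is not None else geno.allele_freq
    rng = _rng(params.seed, 1)

    factor = _psd_factor(params.genetic_cov, m)
    betas = rng.standard_normal((m, 3)) @ factor.T  # cov = genetic_cov / m

    denom = np.sqrt(2.0 * p * (1.0 - p))
    scores = np.empty((trios.n_trios, 3))
    for k, rows in enumerate((trios.offspring, trios.mother, trios.father)):
        z = (geno.dosages[rows] - 2.0 * p) / denom
        scores[:, k] = z @ betas[:, k]

    eps = rng.normal(0.0, np.sqrt(params.resid_var), size=trios.n_trios)
    y = (
        params.intercept
        + params.sex_effect * trios.offspring_sex
        + scores.sum(axis=1)
        + eps
    )
    table = pd.DataFrame(
        {
            "trio": np.arange(trios.n_trios),
            "sex": trios.offspring_sex,
            "score": y,
        }
    )
    return PhenotypeSim(table=table, betas=betas, genetic_scores=scores,
                        residuals=eps)


def simulate_items(
    scores,
    n_items: int,
    missing_rate: float = 0.0,
    seed: int = 0,
    scale: str = "conduct",
) -> pd.DataFrame:
    """Discretize latent scores into ordinal 1-4 items with MCAR missingness.

    Each item carries three fixed cut points; the cut points of all items
    tile ``(0, 1)`` evenly, so the item sum is a monotone step function of
    the min-max-scaled latent score (rank-concordant by construction).
    This is a fixture generator for scoring pipelines, not a psychometric
    model of any particular rating instrument.  Randomness enters only
    through the missing-completely-at-random mask.
    """
    if n_items < 1:
        raise ConfigurationError("n_items must be at least 1")
    if not (0.0 <= missing_rate < 1.0):
        raise ConfigurationError("missing_rate must lie in [0, 1)")
    if isinstance(scores, pd.DataFrame):
        latent = scores["score"].to_numpy(dtype=float)
    else:
        latent = np.asarray(scores, dtype=float)
    n = latent.shape[0]

    span = latent.max() - latent.min()
    q = np.zeros(n) if span == 0 else (latent - latent.min()) / span

    n_cuts = 3 * n_items
    cuts = (np.arange(1, n_cuts + 1)) / (n_cuts + 1)  # strictly inside (0, 1)
    # item j owns cut points j, j+n_items, j+2*n_items -> all items span the range
    values = np.empty((n, n_items), dtype=float)
    for j in range(n_items):
        own = cuts[j::n_items]
        values[:, j] = 1.0 + (q[:, None] > own[None, :]).sum(axis=1)

    rng = np.random.default_rng(seed)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values[mask] = np.nan

    cols = [f"{scale}_item{j + 1}" for j in range(n_items)]
    out = pd.DataFrame(values, columns=cols)
    out.insert(0, "trio", np.arange(n))
    return out
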