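"""Genomic relatedness matrices and trio role-blocks.

The GRM entry for individuals j and k averages standardized-genotype
cross-products over SNPs,

    A_jk = (1/M) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

the Yang et al. SNP-based relatedness estimator.  With missing calls the
average runs over the SNPs where both calls are present (pairwise-complete
M).  The six role-blocks of the GRM (offspring/mother/father crossed with
themselves) drive the covariance structure of the trio variance-component
model: parent-offspring block diagonals are 1/2 in expectation, the
mother-father diagonal 0 for unrelated matings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import blas

from .data import GenotypeData, InputError, TrioIndex

__all__ = ["GRM", "GRMSet", "compute_grm", "trio_grm_blocks", "prune_relatedness"]


@dataclass
class GRM:
    """Symmetric relatedness estimate with the SNP count it is built from."""

    values: np.ndarray
    n_snps_used: int
    ids: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class GRMSet:
    """The six N x N trio role-blocks of an underlying GRM.

    ``a_oo``, ``a_mm``, ``a_pp`` are symmetric; ``a_om``, ``a_op``,
    ``a_mp`` are general (row role first: ``a_om[i, j]`` relates
    offspring i to mother j).
    """

    a_oo: np.ndarray
    a_mm: np.ndarray
    a_pp: np.ndarray
    a_om: np.ndarray
    a_op: np.ndarray
    a_mp: np.ndarray

    @property
    def n_trios(self) -> int:
        return self.a_oo.shape[0]


def _syrk(z: np.ndarray) -> np.ndarray:
    """z @ z.T via rank-k update, symmetrized."""
    g = blas.dsyrk(1.0, np.asfortranarray(z), lower=0)
    return g + np.triu(g, 1).T


def compute_grm(
    geno: GenotypeData,
    allele_freq: np.ndarray | None = None,
    founders: np.ndarray | None = None,
) -> GRM:
    """Compute the SNP-based genomic relatedness matrix.

    Allele frequencies default to ``geno.allele_freq``; pass ``founders``
    (row indices, e.g. the parents of a trio sample) to estimate them from
    founders only, avoiding double-counting of transmitted alleles.
    Frequencies must be strictly inside (0, 1): monomorphic SNPs belong to
    QC, not here.
    """
    if allele_freq is None:
        if founders is not None:
            with np.errstate(invalid="ignore"):
                allele_freq = np.nanmean(geno.dosages[founders], axis=0) / 2.0
        else:
            allele_freq = geno.allele_freq
    p = np.asarray(allele_freq, dtype=float)
    if p.shape != (geno.n_snps,):
        raise InputError("allele_freq length must match n_snps")
    if not ((p > 0) & (p < 1)).all():
        bad = np.where((p <= 0) | (p >= 1))[0][:5]
        raise InputError(
            f"allele frequencies must be strictly in (0, 1); offending SNPs "
            f"(QC should have removed them): {bad.tolist()}"
        )

    denom = np.sqrt(2.0 * p * (1.0 - p))
    z = (geno.dosages - 2.0 * p) / denom
    missing = np.isnan(z)
    if missing.any():
        z = np.where(missing, 0.0, z)
        called = (~missing).astype(float)
        counts = called @ called.T  # pairwise-complete SNP counts
        counts = np.maximum(counts, 1.0)
        values = _syrk(z) / counts
    else:
        values = _syrk(z) / geno.n_snps
    return GRM(values=values, n_snps_used=geno.n_snps, ids=geno.ids)


def trio_grm_blocks(grm: GRM, trios: TrioIndex) -> GRMSet:
    """Extract the six role-blocks of a GRM for a trio index."""
    n = grm.n
    members = trios.members()
    if members.size and (members.max() >= n or members.min() < 0):
        bad = members[(members >= n) | (members < 0)]
        raise InputError(f"trio rows missing from GRM: {sorted(set(bad.tolist()))}")
    o, m, f = trios.offspring, trios.mother, trios.father
    v = grm.values
    return GRMSet(
        a_oo=v[np.ix_(o, o)],
        a_mm=v[np.ix_(m, m)],
        a_pp=v[np.ix_(f, f)],
        a_om=v[np.ix_(o, m)],
        a_op=v[np.ix_(o, f)],
        a_mp=v[np.ix_(m, f)],
    )


def prune_relatedness(
    grm: GRM, trios: TrioIndex, threshold: float = 0.10
) -> TrioIndex:
    """Drop trios until no residual relatedness exceeds ``threshold``.

    A pair violates the threshold when its GRM entry exceeds it, except
    for within-trio parent-offspring pairs (expected relatedness 1/2,
    exempt by design).  Within-trio mother-father pairs and all
    cross-trio pairs count.  Removal is greedy: repeatedly drop the trio
    containing the individual with the most above-threshold edges, ties
    broken by the larger maximum edge, then by the lower trio index.
    """
    if threshold <= 0:
        raise InputError("threshold must be positive")
    n = trios.n_trios
    members = trios.members()  # offspring block, mother block, father block
    if members.size and (members.max() >= grm.n or members.min() < 0):
        raise InputError("trio rows missing from GRM")
    a = grm.values[np.ix_(members, members)]
    trio_of = np.tile(np.arange(n), 3)

    viol = a > threshold
    np.fill_diagonal(viol, False)
    # exempt within-trio parent-offspring pairs (o-m and o-f, both directions)
    idx = np.arange(n)
    for parent_block in (1, 2):
        viol[idx, parent_block * n + idx] = False
        viol[parent_block * n + idx, idx] = False

    active = np.ones(n, dtype=bool)
    edges = np.where(viol, a, -np.inf)
    while True:
        counts = viol.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        top = counts.max()
        cand = np.where(counts == top)[0]
        max_edge = edges[cand].max(axis=1)
        cand = cand[max_edge == max_edge.max()]
        drop_trio = trio_of[cand].min()
        rows = [drop_trio, n + drop_trio, 2 * n + drop_trio]
        viol[rows, :] = False
        viol[:, rows] = False
        edges[rows, :] = -np.inf
        edges[:, rows] = -np.inf
        active[drop_trio] = False
    return trios.subset(active)
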