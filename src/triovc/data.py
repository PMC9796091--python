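"""Core containers for trio-structured genotype and phenotype data.

The analysis unit throughout the package is the *trio*: a genotyped
offspring together with both genotyped parents.  Genotypes are stored as
allele-count dosages in ``[0, 2]`` (``NaN`` marks a missing call); trio
structure is a triple of row indices into the dosage matrix plus the
offspring's sex, which enters the phenotype model as a fixed effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Invalid user-supplied parameters (sizes, ranges, non-PSD matrices)."""


class InputError(ValueError):
    """Invalid or inconsistent input data."""


def _as_str_ids(ids, n: int, prefix: str) -> np.ndarray:
    if ids is None:
        width = len(str(max(n - 1, 1)))
        return np.array([f"{prefix}{i:0{width}d}" for i in range(n)])
    ids = np.asarray(ids, dtype=object)
    if ids.shape != (n,):
        raise InputError(f"expected {n} ids, got shape {ids.shape}")
    if len(set(ids)) != n:
        raise InputError("ids must be unique")
    return ids


@dataclass
class GenotypeData:
    """SNP dosage matrix with per-SNP allele frequencies and a missingness mask.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_snps)`` array of allele-count dosages in
        ``[0, 2]``; ``NaN`` encodes a missing call.  Hard calls are the
        integers ``{0, 1, 2}``.
    ids
        Unique individual identifiers (generated if omitted).
    snp_ids
        Unique variant identifiers (generated if omitted).
    allele_freq
        Per-SNP frequency of the counted allele.  If omitted it is
        estimated as ``mean(dosage) / 2`` over non-missing entries.
    pop_freq
        Optional generating (population) allele frequencies.  Filled in by
        the simulator; estimators never require it.
    """

    dosages: np.ndarray
    ids: np.ndarray = None
    snp_ids: np.ndarray = None
    allele_freq: np.ndarray = None
    pop_freq: np.ndarray | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise InputError("dosages must be a 2-D (individuals x SNPs) array")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise InputError(
                f"dosage out of [0, 2] at individual {i}, SNP {j}: "
                f"{self.dosages[i, j]!r}"
            )
        n, m = self.dosages.shape
        self.ids = _as_str_ids(self.ids, n, "ind")
        self.snp_ids = _as_str_ids(self.snp_ids, m, "snp")
        if self.allele_freq is None:
            with np.errstate(invalid="ignore"):
                self.allele_freq = np.nanmean(self.dosages, axis=0) / 2.0
        else:
            self.allele_freq = np.asarray(self.allele_freq, dtype=float)
            if self.allele_freq.shape != (m,):
                raise InputError("allele_freq length must match n_snps")
        if self.pop_freq is not None:
            self.pop_freq = np.asarray(self.pop_freq, dtype=float)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, m)`` array, True where the call is missing."""
        return np.isnan(self.dosages)

    def select_variants(self, keep: np.ndarray) -> "GenotypeData":
        """Subset to the variants selected by a boolean mask or index array."""
        keep = np.asarray(keep)
        return GenotypeData(
            dosages=self.dosages[:, keep],
            ids=self.ids,
            snp_ids=self.snp_ids[keep],
            pop_freq=None if self.pop_freq is None else self.pop_freq[keep],
        )

    def select_individuals(self, keep: np.ndarray) -> "GenotypeData":
        """Subset to the individuals selected by a boolean mask or index array."""
        keep = np.asarray(keep)
        return GenotypeData(
            dosages=self.dosages[keep, :],
            ids=self.ids[keep],
            snp_ids=self.snp_ids,
            pop_freq=self.pop_freq,
        )


@dataclass
class TrioIndex:
    """Row indices of (offspring, mother, father) for each trio.

    ``offspring_sex`` is the binary fixed-effect covariate for the child
    (1 = male, 0 = female).
    """

    offspring: np.ndarray
    mother: np.ndarray
    father: np.ndarray
    offspring_sex: np.ndarray = None

    def __post_init__(self):
        self.offspring = np.asarray(self.offspring, dtype=int)
        self.mother = np.asarray(self.mother, dtype=int)
        self.father = np.asarray(self.father, dtype=int)
        n = self.offspring.shape[0]
        if not (self.mother.shape == self.father.shape == (n,)):
            raise InputError("offspring/mother/father index arrays differ in length")
        if self.offspring_sex is None:
            self.offspring_sex = np.zeros(n, dtype=int)
        else:
            self.offspring_sex = np.asarray(self.offspring_sex, dtype=int)
            if self.offspring_sex.shape != (n,):
                raise InputError("offspring_sex length must match trio count")
        all_rows = np.concatenate([self.offspring, self.mother, self.father])
        if len(np.unique(all_rows)) != 3 * n:
            raise InputError(
                "trio roles must be distinct rows and no row may appear twice"
            )

    @property
    def n_trios(self) -> int:
        return self.offspring.shape[0]

    def members(self) -> np.ndarray:
        """All member rows, offspring block first, then mothers, then fathers."""
        return np.concatenate([self.offspring, self.mother, self.father])

    def validate_against(self, n_individuals: int) -> None:
        if self.members().max(initial=-1) >= n_individuals or self.members().min(
            initial=0
        ) < 0:
            raise InputError("trio index out of range for genotype matrix")

    def subset(self, keep: np.ndarray) -> "TrioIndex":
        keep = np.asarray(keep)
        if keep.size == 0:
            keep = keep.astype(int)
        return TrioIndex(
            offspring=self.offspring[keep],
            mother=self.mother[keep],
            father=self.father[keep],
            offspring_sex=self.offspring_sex[keep],
        )
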