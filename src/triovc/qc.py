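"""Post-imputation genotype quality control for trio data.

Variant filters (minor allele frequency, call rate, Hardy-Weinberg
equilibrium), sample filters (call rate, heterozygosity F statistic) and
a Mendelian-error scan over trios.  Each excluded unit is labelled with
the first criterion it failed, in a fixed evaluation order, so reports
are reproducible and exclusions sum across reasons.

Dosages within ``hard_call_cut`` of an integer are treated as hard calls;
softer dosages are skipped (and counted) wherever genotype classes are
needed (HWE, heterozygosity, Mendelian logic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import ConfigurationError, GenotypeData, InputError, TrioIndex

__all__ = [
    "QCThresholds",
    "QCReport",
    "hwe_test",
    "variant_filters",
    "sample_filters",
    "mendelian_error_scan",
    "MENDELIAN_ERROR_TABLE",
]


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; defaults are the conventional post-imputation values
    (MAF > 1%, call rate > 98% for variants and samples, HWE p < .001,
    |F-het| <= 0.2)."""

    maf_min: float = 0.01
    call_rate_min: float = 0.98
    hwe_alpha: float = 0.001
    fhet_bound: float = 0.2
    hard_call_cut: float = 0.1

    def __post_init__(self):
        if not (0 <= self.maf_min < 0.5):
            raise ConfigurationError("maf_min must lie in [0, 0.5)")
        if not (0 < self.call_rate_min <= 1):
            raise ConfigurationError("call_rate_min must lie in (0, 1]")
        if not (0 < self.hwe_alpha < 1):
            raise ConfigurationError("hwe_alpha must lie in (0, 1)")
        if not (0 < self.fhet_bound <= 1):
            raise ConfigurationError("fhet_bound must lie in (0, 1]")
        if not (0 < self.hard_call_cut <= 0.5):
            raise ConfigurationError("hard_call_cut must lie in (0, 0.5]")


@dataclass
class QCReport:
    """Pass/fail decisions with one first-failing criterion per excluded unit."""

    variant_pass: np.ndarray | None = None
    variant_reason: np.ndarray | None = None  # None where passing
    sample_pass: np.ndarray | None = None
    sample_reason: np.ndarray | None = None
    trio_mendel_errors: np.ndarray | None = None
    snp_mendel_errors: np.ndarray | None = None
    n_soft_calls_skipped: int = 0
    details: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {}
        if self.variant_pass is not None:
            out["n_variants"] = int(self.variant_pass.size)
            out["n_variants_excluded"] = int((~self.variant_pass).sum())
            reasons = [r for r in self.variant_reason if r is not None]
            out["variant_exclusions"] = {
                r: reasons.count(r) for r in sorted(set(reasons))
            }
        if self.sample_pass is not None:
            out["n_samples"] = int(self.sample_pass.size)
            out["n_samples_excluded"] = int((~self.sample_pass).sum())
            reasons = [r for r in self.sample_reason if r is not None]
            out["sample_exclusions"] = {
                r: reasons.count(r) for r in sorted(set(reasons))
            }
        if self.trio_mendel_errors is not None:
            out["n_mendel_errors"] = int(self.trio_mendel_errors.sum())
            out["n_soft_calls_skipped"] = int(self.n_soft_calls_skipped)
        return out


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-degree-of-freedom chi-square goodness-of-fit test of HWE.

    Expected genotype proportions are p^2, 2pq, q^2 with the allele
    frequency estimated from the counts themselves.  Returns 1.0 for a
    zero statistic (exact HWE proportions or a monomorphic site).
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise InputError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise InputError("total genotype count must be positive")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    nz = expected > 0
    stat = float(((counts[nz] - expected[nz]) ** 2 / expected[nz]).sum())
    if stat == 0.0:
        return 1.0
    return float(stats.chi2.sf(stat, df=1))


def _hard_calls(dosages: np.ndarray, cut: float) -> tuple[np.ndarray, np.ndarray]:
    """Integer hard calls and a validity mask (missing or soft -> invalid)."""
    rounded = np.rint(dosages)
    with np.errstate(invalid="ignore"):
        hard = np.abs(dosages - rounded) < cut
    hard &= ~np.isnan(dosages)
    calls = np.where(hard, rounded, 0).astype(np.int8)
    return calls, hard


def variant_filters(
    geno: GenotypeData,
    thresholds: QCThresholds = QCThresholds(),
    trios: TrioIndex | None = None,
) -> QCReport:
    """Flag variants failing MAF, call-rate or HWE criteria.

    Evaluation order for the first-failing label is MAF, then call rate,
    then HWE.  When trio structure is supplied the HWE test uses founder
    (parental) genotypes only, since offspring genotypes duplicate
    parental alleles and are not independent draws from the population.
    """
    if geno.n_individuals == 0 or geno.n_snps == 0:
        raise InputError("variant_filters requires at least one sample and variant")
    n, m = geno.dosages.shape
    freq = geno.allele_freq
    maf = np.minimum(freq, 1 - freq)
    call_rate = 1.0 - np.isnan(geno.dosages).mean(axis=0)

    if trios is not None:
        trios.validate_against(n)
        hwe_rows = np.concatenate([trios.mother, trios.father])
    else:
        hwe_rows = np.arange(n)
    calls, hard = _hard_calls(geno.dosages[hwe_rows], thresholds.hard_call_cut)
    hwe_p = np.ones(m)
    for j in range(m):
        h = hard[:, j]
        if not h.any():
            continue
        c = calls[h, j]
        hwe_p[j] = hwe_test(
            int((c == 2).sum()), int((c == 1).sum()), int((c == 0).sum())
        )

    reason = np.array([None] * m, dtype=object)
    reason[hwe_p < thresholds.hwe_alpha] = "hwe"
    reason[call_rate < thresholds.call_rate_min] = "call_rate"
    reason[maf < thresholds.maf_min] = "maf"
    passed = np.array([r is None for r in reason])
    return QCReport(
        variant_pass=passed,
        variant_reason=reason,
        details={"maf": maf, "call_rate": call_rate, "hwe_p": hwe_p},
    )


def sample_filters(
    geno: GenotypeData, thresholds: QCThresholds = QCThresholds()
) -> QCReport:
    """Flag samples with low call rate or outlying heterozygosity.

    The heterozygosity statistic is ``F = 1 - observed_het / expected_het``
    with the expectation ``sum 2 p (1 - p)`` over the sample's called
    SNPs; samples with ``|F|`` above ``fhet_bound`` are excluded.  A
    sample whose expected heterozygosity is zero is degenerate and
    excluded with its own reason.
    """
    if geno.n_individuals == 0 or geno.n_snps == 0:
        raise InputError("sample_filters requires at least one sample and variant")
    p = geno.allele_freq
    calls, hard = _hard_calls(geno.dosages, thresholds.hard_call_cut)
    called = ~np.isnan(geno.dosages)
    call_rate = called.mean(axis=1)

    exp_het = (hard * (2 * p * (1 - p))[None, :]).sum(axis=1)
    obs_het = ((calls == 1) & hard).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fhet = np.where(exp_het > 0, 1.0 - obs_het / exp_het, np.nan)

    n = geno.n_individuals
    reason = np.array([None] * n, dtype=object)
    reason[np.abs(fhet) > thresholds.fhet_bound] = "fhet"
    reason[exp_het <= 0] = "degenerate_heterozygosity"
    reason[call_rate < thresholds.call_rate_min] = "call_rate"
    passed = np.array([r is None for r in reason])
    return QCReport(
        sample_pass=passed,
        sample_reason=reason,
        details={"call_rate": call_rate, "fhet": fhet, "expected_het": exp_het},
    )


def _mendelian_error_table() -> np.ndarray:
    """Brute-force gamete enumeration: err[father, mother, offspring]."""
    gametes = {0: [0], 1: [0, 1], 2: [1]}
    err = np.ones((3, 3, 3), dtype=bool)
    for f in range(3):
        for m_ in range(3):
            for gf in gametes[f]:
                for gm in gametes[m_]:
                    err[f, m_, gf + gm] = False
    return err


MENDELIAN_ERROR_TABLE = _mendelian_error_table()


def mendelian_error_scan(
    geno: GenotypeData,
    trios: TrioIndex,
    thresholds: QCThresholds = QCThresholds(),
) -> QCReport:
    """Count (trio, SNP) combinations impossible under Mendelian transmission.

    Only hard-callable genotypes participate; entries where any trio
    member is missing or soft-called are skipped and tallied in
    ``n_soft_calls_skipped``.
    """
    trios.validate_against(geno.n_individuals)
    cut = thresholds.hard_call_cut
    o_calls, o_hard = _hard_calls(geno.dosages[trios.offspring], cut)
    m_calls, m_hard = _hard_calls(geno.dosages[trios.mother], cut)
    f_calls, f_hard = _hard_calls(geno.dosages[trios.father], cut)

    usable = o_hard & m_hard & f_hard
    err = MENDELIAN_ERROR_TABLE[f_calls, m_calls, o_calls] & usable
    return QCReport(
        trio_mendel_errors=err.sum(axis=1),
        snp_mendel_errors=err.sum(axis=0),
        n_soft_calls_skipped=int((~usable).sum()),
        details={"error_mask": err},
    )
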