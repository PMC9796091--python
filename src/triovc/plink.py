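"""File interchange: PLINK bed/bim/fam and GCTA binary GRM formats.

The PLINK .bed file is SNP-major, two bits per call (00 homozygous A1,
10 heterozygous, 11 homozygous A2, 01 missing); dosages here count the
A1 allele.  Trio structure is encoded in the .fam father/mother ID
columns.  The GCTA GRM format stores the lower triangle (diagonal
included) of the relatedness matrix and the per-pair SNP counts as
little-endian float32, with a two-column id file.

Phenotype tables travel as plain TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenotypeData, InputError, TrioIndex
from .relatedness import GRM

__all__ = [
    "write_plink",
    "read_plink",
    "write_grm",
    "read_grm",
    "write_phenotypes",
    "read_phenotypes",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code per A1-allele dosage: 2 -> 00, missing -> 01, 1 -> 10, 0 -> 11
_CODE_FROM_DOSAGE = {2: 0b00, 1: 0b10, 0: 0b11}
_DOSAGE_FROM_CODE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}


def write_plink(
    geno: GenotypeData, trios: TrioIndex | None, prefix: str | Path
) -> None:
    """Write hard-called genotypes to ``prefix``.bed/.bim/.fam.

    Soft dosages are rounded to the nearest integer; missing stays
    missing.  When a trio index is given, fam rows of offspring carry
    their father's and mother's IIDs and the family ID groups the trio.
    """
    prefix = Path(prefix)
    n, m = geno.dosages.shape
    dos = geno.dosages

    role = {}
    if trios is not None:
        trios.validate_against(n)
        for t in range(trios.n_trios):
            fid = f"T{t}"
            o, mo, fa = trios.offspring[t], trios.mother[t], trios.father[t]
            sex_code = 1 if trios.offspring_sex[t] == 1 else 2
            role[o] = (fid, geno.ids[fa], geno.ids[mo], sex_code)
            role[mo] = (fid, "0", "0", 2)
            role[fa] = (fid, "0", "0", 1)

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i in range(n):
            fid, father, mother, sex = role.get(i, (f"F{i}", "0", "0", 0))
            fh.write(f"{fid}\t{geno.ids[i]}\t{father}\t{mother}\t{sex}\t-9\n")

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(m):
            fh.write(f"1\t{geno.snp_ids[j]}\t0\t{j + 1}\tA\tB\n")

    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        buf = np.zeros(n_bytes, dtype=np.uint8)
        for j in range(m):
            buf[:] = 0
            col = dos[:, j]
            for i in range(n):
                d = col[i]
                code = 0b01 if np.isnan(d) else _CODE_FROM_DOSAGE[int(round(d))]
                buf[i >> 2] |= code << ((i & 3) * 2)
            fh.write(buf.tobytes())


def read_plink(prefix: str | Path) -> tuple[GenotypeData, TrioIndex | None]:
    """Read ``prefix``.bed/.bim/.fam; reconstruct trios from fam parent IDs.

    Returns ``(genotypes, trios)``; ``trios`` is ``None`` when the fam
    file encodes no complete parent-offspring trio.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype=str,
    )
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise InputError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    body = raw[3:]
    if body.size != n_bytes * m:
        raise InputError("bed file size inconsistent with fam/bim dimensions")
    body = body.reshape(m, n_bytes)

    codes = np.empty((m, n), dtype=np.uint8)
    for shift in range(4):
        lane = (body >> (2 * shift)) & 0b11
        codes[:, shift::4] = lane[:, : len(range(shift, n, 4))]
    lookup = np.array([2.0, np.nan, 1.0, 0.0])
    dosages = lookup[codes].T  # (n, m)

    geno = GenotypeData(
        dosages=dosages,
        ids=fam["iid"].to_numpy(dtype=object),
        snp_ids=bim["snp"].to_numpy(dtype=object),
    )

    row_of = {iid: i for i, iid in enumerate(fam["iid"])}
    off, mot, fat, sex = [], [], [], []
    for i, rec in fam.iterrows():
        if rec["father"] in row_of and rec["mother"] in row_of:
            off.append(i)
            fat.append(row_of[rec["father"]])
            mot.append(row_of[rec["mother"]])
            sex.append(1 if rec["sex"] == "1" else 0)
    trios = None
    if off:
        trios = TrioIndex(
            offspring=np.array(off),
            mother=np.array(mot),
            father=np.array(fat),
            offspring_sex=np.array(sex),
        )
    return geno, trios


def _tri_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = np.tril_indices(n)
    return rows, cols


def write_grm(grm: GRM, prefix: str | Path) -> None:
    """Write ``prefix``.grm.bin / .grm.N.bin / .grm.id (GCTA layout)."""
    prefix = Path(prefix)
    rows, cols = _tri_indices(grm.n)
    grm.values[rows, cols].astype("<f4").tofile(f"{prefix}.grm.bin")
    np.full(rows.size, grm.n_snps_used, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for iid in grm.ids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm(prefix: str | Path) -> GRM:
    """Read a GCTA-format GRM written by :func:`write_grm` (or GCTA itself)."""
    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None)[1].to_numpy(
        dtype=object
    )
    n = ids.size
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4").astype(float)
    rows, cols = _tri_indices(n)
    if tri.size != rows.size:
        raise InputError("grm.bin size inconsistent with grm.id")
    values = np.zeros((n, n))
    values[rows, cols] = tri
    values[cols, rows] = tri
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    n_snps = int(counts.max()) if counts.size else 0
    return GRM(values=values, n_snps_used=n_snps, ids=ids)


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    """Write a phenotype table as TSV."""
    table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a TSV phenotype table."""
    return pd.read_csv(path, sep="\t")
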