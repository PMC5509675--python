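"""PLINK bed/bim/fam (and covariate table) reading and writing.

The bed file is SNP-major with the standard 2-bit encoding; per variant,
samples are packed four to a byte, sample 0 in the lowest two bits:

    00 -> two copies of allele 1 (dosage 2)
    01 -> missing
    10 -> heterozygote (dosage 1)
    11 -> two copies of allele 2 (dosage 0)

Dosages count allele 1 (A1), the minor allele by PLINK convention; the
fixture writer always emits the simulated minor allele as A1, so dosage is
the minor-allele count on anything the package writes itself.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datatypes import CohortStudy, PlinkFormatError

_BED_MAGIC = b"\x6c\x1b\x01"  # third byte: SNP-major

# fam phenotype dialect: 1=control, 2=case, 0/-9=missing
_FAM_PHENO_TO_STATUS = {1: 0.0, 2: 1.0, 0: np.nan, -9: np.nan}


def read_fam(path: str) -> pd.DataFrame:
    fam = pd.read_csv(path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"fid": str, "iid": str})
    pheno = fam["pheno"].astype(float)
    mapped = pheno.map(lambda v: _FAM_PHENO_TO_STATUS.get(int(v), np.nan)
                       if not np.isnan(v) else np.nan)
    out = pd.DataFrame({
        "fid": fam["fid"], "iid": fam["iid"],
        "sex": fam["sex"].astype(int),
        "phenotype": mapped.astype(float),
        "cohort": "cohort0",
    })
    return out


def read_bim(path: str) -> pd.DataFrame:
    bim = pd.read_csv(path, sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "snp": str, "a1": str, "a2": str})
    return bim[["snp", "chrom", "pos", "a1", "a2"]]


def read_plink(path_prefix: str, covar: str | None = None) -> CohortStudy:
    """Read a bed/bim/fam triple into a :class:`CohortStudy`.

    Parameters
    ----------
    path_prefix
        Path without the ``.bed``/``.bim``/``.fam`` extension.
    covar
        Optional whitespace-delimited covariate file with FID/IID header;
        a ``cohort`` column, if present, overrides the default label.
    """
    bed_path, bim_path, fam_path = (path_prefix + ext for ext in (".bed", ".bim", ".fam"))
    for p in (bed_path, bim_path, fam_path):
        if not os.path.exists(p):
            raise PlinkFormatError(f"missing PLINK file: {p}")
    samples = read_fam(fam_path)
    variants = read_bim(bim_path)
    n, m = len(samples), len(variants)

    with open(bed_path, "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise PlinkFormatError(
                f"{bed_path}: bad magic bytes {magic!r} (expected SNP-major bed)")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if data.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{bed_path}: truncated or oversized ({data.size} bytes, "
            f"expected {bytes_per_snp * m} for {n} samples x {m} variants)")

    codes = data.reshape(m, bytes_per_snp)
    # unpack 2-bit fields, sample 0 in the lowest bits
    shifts = np.arange(4, dtype=np.uint8) * 2
    two_bit = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
    two_bit = two_bit.reshape(m, bytes_per_snp * 4)[:, :n]
    # 00 -> 2 copies of A1, 10 -> 1, 11 -> 0, 01 -> missing
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    genotypes = lut[two_bit].T.copy()  # samples x variants

    study = CohortStudy(genotypes, samples, variants)
    if covar is not None:
        cov = read_covar(covar)
        study = attach_covariates(study, cov)
    return study


def read_covar(path: str) -> pd.DataFrame:
    cov = pd.read_csv(path, sep=r"\s+", dtype={"FID": str, "IID": str})
    if not {"FID", "IID"}.issubset(cov.columns):
        raise PlinkFormatError(f"{path}: covariate file needs FID/IID header")
    return cov


def attach_covariates(study: CohortStudy, cov: pd.DataFrame) -> CohortStudy:
    samples = study.samples.merge(
        cov.rename(columns={"FID": "fid", "IID": "iid"}),
        on=["fid", "iid"], how="left", suffixes=("", "_cov"))
    if "cohort_cov" in samples.columns:
        samples["cohort"] = samples.pop("cohort_cov")
    elif "COHORT" in samples.columns:
        samples["cohort"] = samples.pop("COHORT").astype(str)
    if "SEX" in samples.columns:
        samples["sex"] = samples.pop("SEX").astype(int)
    return CohortStudy(study.genotypes, samples, study.variants, study.truth)


def write_plink(study: CohortStudy, path_prefix: str,
                write_covar: bool = True) -> None:
    """Write bed/bim/fam (plus a PLINK-dialect covariate table with sex and
    cohort) for a study."""
    n, m = study.n_samples, study.n_variants
    if n < 1 or m < 1:
        raise ValueError("cannot write an empty study")

    # fam: 1=control, 2=case, -9=missing
    pheno = study.samples["phenotype"].map(
        lambda v: -9 if pd.isna(v) else (2 if v == 1.0 else 1))
    fam = pd.DataFrame({
        "fid": study.samples["fid"], "iid": study.samples["iid"],
        "father": 0, "mother": 0,
        "sex": study.samples["sex"].astype(int), "pheno": pheno.astype(int),
    })
    fam.to_csv(path_prefix + ".fam", sep=" ", header=False, index=False)

    bim = pd.DataFrame({
        "chrom": study.variants["chrom"], "snp": study.variants["snp"],
        "cm": 0, "pos": study.variants["pos"].astype(int),
        "a1": study.variants["a1"], "a2": study.variants["a2"],
    })
    bim.to_csv(path_prefix + ".bim", sep="\t", header=False, index=False)

    g = study.genotypes.T  # SNP-major
    code = np.full(g.shape, 0b01, dtype=np.uint8)  # missing
    code[g == 2] = 0b00
    code[g == 1] = 0b10
    code[g == 0] = 0b11
    bytes_per_snp = (n + 3) // 4
    padded = np.full((m, bytes_per_snp * 4), 0b01, dtype=np.uint8)
    padded[:, :n] = code
    packed = (padded[:, 0::4] | (padded[:, 1::4] << 2)
              | (padded[:, 2::4] << 4) | (padded[:, 3::4] << 6))
    with open(path_prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())

    if write_covar:
        cov = pd.DataFrame({
            "FID": study.samples["fid"], "IID": study.samples["iid"],
            "SEX": study.samples["sex"].astype(int),
            "COHORT": study.samples["cohort"],
        })
        cov.to_csv(path_prefix + ".cov", sep=" ", index=False)


def write_grm_gz(grm, path_prefix: str) -> None:
    """Write a GRM in the GCTA text dialect: ``.grm.gz``-style pair list
    (written uncompressed as ``.grm.txt``) plus ``.grm.id``."""
    n = grm.n_samples
    rows = []
    for j in range(n):
        for k in range(j + 1):
            rows.append((j + 1, k + 1, grm.m_snps_used, grm.matrix[j, k]))
    pd.DataFrame(rows).to_csv(path_prefix + ".grm.txt", sep="\t",
                              header=False, index=False,
                              float_format="%.8g")
    ids = pd.DataFrame({"fid": grm.sample_ids, "iid": grm.sample_ids})
    ids.to_csv(path_prefix + ".grm.id", sep="\t", header=False, index=False)


def read_grm_gz(path_prefix: str):
    from .datatypes import GRM

    ids = pd.read_csv(path_prefix + ".grm.id", sep="\t", header=None,
                      names=["fid", "iid"], dtype=str)
    n = len(ids)
    tab = pd.read_csv(path_prefix + ".grm.txt", sep="\t", header=None,
                      names=["j", "k", "m", "value"])
    mat = np.zeros((n, n))
    j = tab["j"].to_numpy() - 1
    k = tab["k"].to_numpy() - 1
    mat[j, k] = tab["value"].to_numpy()
    mat[k, j] = tab["value"].to_numpy()
    return GRM(mat, pd.Index(ids["iid"]), int(tab["m"].iloc[0]))
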