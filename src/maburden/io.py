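"""Readers and writers: PLINK 1 binary (bed/bim/fam) and a plain-text dialect.

PLINK conventions followed here:

* ``.bed`` is SNP-major v1.00 (magic bytes ``0x6c 0x1b 0x01``); each genotype
  is 2 bits, packed 4 per byte, low bits first.  Code 0b00 = homozygous A1,
  0b10 = heterozygous, 0b11 = homozygous A2, 0b01 = missing.
* The *counted* allele is A1 (the first allele column of the ``.bim``), so
  code 0b00 decodes to dosage 2 and 0b11 to dosage 0.
* ``.fam`` phenotype uses 1 = control, 2 = case; anything else is an error.

The text dialect is a directory of three tab-separated files:
``genotypes.tsv`` (``subject_id`` + one column per SNP, values 0/1/2/NA),
``snps.tsv`` (``snp_id  chrom  pos  a1  a2`` plus any annotation columns) and
``phenotypes.tsv`` (``subject_id  status [sex]`` with status control/case).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (AUTOSOMES, Cohort, GenotypeMatrix, MaburdenError,
                         Phenotype, validate_snp_table)

log = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> dosage of A1; 0b01 is missing
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])

GENO_FILE = "genotypes.tsv"
SNP_FILE = "snps.tsv"
PHENO_FILE = "phenotypes.tsv"


# ---------------------------------------------------------------------------
# PLINK binary
# ---------------------------------------------------------------------------

def write_plink(cohort: Cohort, prefix: str | Path) -> None:
    """Write ``prefix``.bed/.bim/.fam for a cohort."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    snps = cohort.snps
    bim = pd.DataFrame({
        "chrom": snps["chrom"], "snp_id": snps["snp_id"], "cm": 0,
        "pos": snps["pos"], "a1": snps["a1"], "a2": snps["a2"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    phen = cohort.phenotype
    sex = phen.sex if phen.sex is not None else np.zeros(phen.status.size, int)
    fam = pd.DataFrame({
        "fid": phen.subject_ids, "iid": phen.subject_ids,
        "father": 0, "mother": 0, "sex": np.asarray(sex, int),
        "pheno": phen.status + 1,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    d = cohort.genotypes.dosage  # (n, m)
    n = d.shape[0]
    codes = np.full(d.shape, 1, dtype=np.uint8)  # missing
    codes[d == 2.0] = 0b00
    codes[d == 1.0] = 0b10
    codes[d == 0.0] = 0b11
    n_pad = (-n) % 4
    if n_pad:
        codes = np.vstack([codes, np.zeros((n_pad, d.shape[1]), np.uint8)])
    quads = codes.T.reshape(d.shape[1], -1, 4)  # SNP-major
    packed = (quads[:, :, 0] | (quads[:, :, 1] << 2)
              | (quads[:, :, 2] << 4) | (quads[:, :, 3] << 6)).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink(bed_path: str | Path, bim_path: str | Path | None = None,
               fam_path: str | Path | None = None) -> Cohort:
    """Read a PLINK 1 fileset into a :class:`Cohort`.

    Non-autosomal records are skipped with a warning.  Raises on a bad magic
    number, a truncated ``.bed``, or phenotype codes outside {1, 2}.
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")

    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
                      dtype={"snp_id": str, "a1": str, "a2": str})
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"iid": str})
    if not np.isin(fam["pheno"], (1, 2)).all():
        raise MaburdenError("fam phenotype codes must be 1 (control) / 2 (case)")

    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise MaburdenError(f"{bed_path} is not a SNP-major PLINK v1.00 bed file")
    n, m = len(fam), len(bim)
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise MaburdenError(
            f"bed payload {body.size} bytes, expected {bytes_per_snp * m} "
            f"for {n} subjects x {m} SNPs")
    body = body.reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosage = _CODE_TO_DOSAGE[codes[:, :n]].T  # subjects x SNPs

    chrom_num = pd.to_numeric(bim["chrom"], errors="coerce")
    keep = chrom_num.isin(list(AUTOSOMES)).to_numpy()
    if not keep.all():
        dropped = bim.loc[~keep, "snp_id"].tolist()
        warnings.warn(f"skipping {len(dropped)} non-autosomal record(s)")
        log.info("non-autosomal SNPs skipped: %s", dropped)
        bim = bim[keep].reset_index(drop=True)
        dosage = dosage[:, keep]

    snps = bim[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    genotypes = GenotypeMatrix(fam["iid"].to_numpy(object),
                               snps["snp_id"].to_numpy(object), dosage)
    phen = Phenotype(fam["iid"].to_numpy(object),
                     (fam["pheno"] - 1).to_numpy(),
                     fam["sex"].to_numpy())
    return Cohort(genotypes, snps, phen)


# ---------------------------------------------------------------------------
# text dialect
# ---------------------------------------------------------------------------

def write_text(cohort: Cohort, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    g = cohort.genotypes
    geno = pd.DataFrame(g.dosage, columns=list(g.snp_ids))
    geno.insert(0, "subject_id", list(g.subject_ids))
    geno.to_csv(directory / GENO_FILE, sep="\t", index=False,
                na_rep="NA", float_format="%g")
    cohort.snps.to_csv(directory / SNP_FILE, sep="\t", index=False,
                       float_format="%.10g")
    phen = cohort.phenotype
    out = pd.DataFrame({"subject_id": phen.subject_ids,
                        "status": np.where(phen.is_case, "case", "control")})
    if phen.sex is not None:
        out["sex"] = phen.sex
    out.to_csv(directory / PHENO_FILE, sep="\t", index=False)


def read_text(directory: str | Path) -> Cohort:
    directory = Path(directory)
    geno = pd.read_csv(directory / GENO_FILE, sep="\t", dtype={"subject_id": str})
    snps = pd.read_csv(directory / SNP_FILE, sep="\t",
                       dtype={"snp_id": str, "a1": str, "a2": str})
    snps = validate_snp_table(snps)
    phen_df = pd.read_csv(directory / PHENO_FILE, sep="\t",
                          dtype={"subject_id": str, "status": str})
    bad = set(phen_df["status"]) - {"case", "control"}
    if bad:
        raise MaburdenError(f"unknown phenotype status values: {sorted(bad)}")
    subject_ids = geno["subject_id"].to_numpy(object)
    snp_ids = snps["snp_id"].to_numpy(object)
    if list(geno.columns[1:]) != list(snp_ids):
        raise MaburdenError("genotype columns disagree with snps.tsv order")
    dosage = geno[geno.columns[1:]].to_numpy(float)
    genotypes = GenotypeMatrix(subject_ids, snp_ids, dosage)
    sex = phen_df["sex"].to_numpy() if "sex" in phen_df.columns else None
    phen = Phenotype(phen_df["subject_id"].to_numpy(object),
                     (phen_df["status"] == "case").to_numpy(int), sex)
    return Cohort(genotypes, snps, phen)
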