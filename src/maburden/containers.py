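"""Core in-memory containers for case-control SNP genotype data.

A cohort is the triple (genotype matrix, SNP table, phenotype).  Genotype
dosages count copies of each SNP's *counted* allele, which by convention is
the first allele column (``a1``) of the SNP table; missing genotypes are
``NaN``.  Only autosomal biallelic SNPs are representable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES = frozenset(range(1, 23))

#: columns every SNP table must carry, in order
SNP_TABLE_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2"]


class MaburdenError(ValueError):
    """Base error for malformed inputs."""


def validate_snp_table(snps: pd.DataFrame) -> pd.DataFrame:
    """Check the required columns, autosomal chromosomes and biallelic records.

    Returns the table with ``chrom``/``pos`` coerced to integers.
    """
    missing = [c for c in SNP_TABLE_COLUMNS if c not in snps.columns]
    if missing:
        raise MaburdenError(f"SNP table lacks columns: {missing}")
    snps = snps.copy()
    snps["chrom"] = snps["chrom"].astype(int)
    snps["pos"] = snps["pos"].astype(int)
    bad_chrom = set(snps["chrom"]) - AUTOSOMES
    if bad_chrom:
        raise MaburdenError(f"non-autosomal chromosome labels: {sorted(bad_chrom)}")
    same = snps["a1"].astype(str) == snps["a2"].astype(str)
    if same.any():
        raise MaburdenError("SNPs with identical alleles (not biallelic): "
                            f"{snps.loc[same, 'snp_id'].tolist()[:5]}")
    if snps["snp_id"].duplicated().any():
        raise MaburdenError("duplicated snp_id in SNP table")
    return snps


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs dosages of the counted allele, in {0, 1, 2, NaN}."""

    subject_ids: np.ndarray
    snp_ids: np.ndarray
    dosage: np.ndarray  # float, shape (n_subjects, n_snps)

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise MaburdenError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise MaburdenError("dosage values outside {0, 1, 2, NaN}")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise MaburdenError("duplicated subject_id")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def snp_indexer(self, snp_ids) -> np.ndarray:
        """Column indices of the given SNP ids (order preserved)."""
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise MaburdenError(f"unknown snp_id {exc.args[0]!r}") from exc

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.subject_ids, self.snp_ids[index],
                              self.dosage[:, index])

    def take_subjects(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.subject_ids[index], self.snp_ids,
                              self.dosage[index, :])


@dataclass
class Phenotype:
    """Case/control status (1 = case, 0 = control) with optional sex."""

    subject_ids: np.ndarray
    status: np.ndarray  # int8, 0 control / 1 case
    sex: np.ndarray | None = None  # 1 male / 2 female / 0 unknown

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.status.shape != self.subject_ids.shape:
            raise MaburdenError("phenotype status length mismatch")
        if not np.isin(self.status, (0, 1)).all():
            raise MaburdenError("status must be 0 (control) or 1 (case)")
        if self.sex is not None:
            self.sex = np.asarray(self.sex, dtype=np.int8)

    @property
    def is_case(self) -> np.ndarray:
        return self.status == 1

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())

    def aligned_to(self, subject_ids: np.ndarray) -> "Phenotype":
        """Reorder to the given subject ids (all must be present)."""
        order = {s: i for i, s in enumerate(self.subject_ids)}
        try:
            idx = np.array([order[s] for s in subject_ids], dtype=int)
        except KeyError as exc:
            raise MaburdenError(f"subject {exc.args[0]!r} has no phenotype") from exc
        sex = self.sex[idx] if self.sex is not None else None
        return Phenotype(self.subject_ids[idx], self.status[idx], sex)

    def take(self, index: np.ndarray) -> "Phenotype":
        sex = self.sex[index] if self.sex is not None else None
        return Phenotype(self.subject_ids[index], self.status[index], sex)


@dataclass
class Cohort:
    """One case-control cohort: genotypes + SNP table + phenotype."""

    genotypes: GenotypeMatrix
    snps: pd.DataFrame
    phenotype: Phenotype
    name: str = "cohort"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.snps = validate_snp_table(self.snps)
        if not np.array_equal(np.asarray(self.snps["snp_id"], dtype=object),
                              self.genotypes.snp_ids):
            raise MaburdenError("SNP table and genotype matrix disagree on SNP ids")
        self.phenotype = self.phenotype.aligned_to(self.genotypes.subject_ids)
        if self.phenotype.n_cases == 0 or self.phenotype.n_controls == 0:
            raise MaburdenError(f"cohort {self.name!r} needs >=1 case and >=1 control")

    @property
    def n_subjects(self) -> int:
        return self.genotypes.n_subjects

    @property
    def n_snps(self) -> int:
        return self.genotypes.n_snps

    def take_snps(self, index: np.ndarray) -> "Cohort":
        return Cohort(self.genotypes.take_snps(index),
                      self.snps.iloc[index].reset_index(drop=True),
                      self.phenotype, name=self.name, extra=dict(self.extra))

    def take_subjects(self, index: np.ndarray) -> "Cohort":
        return Cohort(self.genotypes.take_subjects(index), self.snps,
                      self.phenotype.take(index), name=self.name,
                      extra=dict(self.extra))
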