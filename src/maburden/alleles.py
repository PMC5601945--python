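"""Minor-allele assignment, per-subject minor-allele content (MAC), and the
elementary two-group tests used to compare burden statistics.

The minor allele of a SNP is the allele with frequency < 0.5 **in the control
cohort** (frequency over non-missing control genotypes).  A SNP whose control
frequency is exactly 0.5 (tie) or 0/1 (monomorphic) is *non-informative* and
excluded from every burden statistic.

MAC is the fraction of a subject's carried alleles that are minor:
``MAC_i = sum_j d_ij / (2 * n_used_i)`` over informative SNPs ``j`` with a
non-missing genotype for subject ``i``, where ``d`` is the minor-allele
dosage.  A literal per-SNP denominator (``/ n_used``) is available as an
option but the per-allele form is the default, matching the scale on which
MAC approximates the mean panel MAF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Cohort, GenotypeMatrix, MaburdenError, Phenotype


@dataclass
class MaAssignment:
    """Per-SNP minor-allele designation derived from a control cohort."""

    snp_ids: np.ndarray
    minor_allele: np.ndarray       # allele label, or "" when non-informative
    maf: np.ndarray                # control MAF in [0, 0.5]
    minor_is_a1: np.ndarray        # bool; orientation of the counted dosage
    informative: np.ndarray        # bool; False for ties / monomorphic / no data

    def __post_init__(self) -> None:
        if not ((self.maf[~np.isnan(self.maf)] >= 0).all()
                and (self.maf[~np.isnan(self.maf)] <= 0.5).all()):
            raise MaburdenError("MAF outside [0, 0.5]")

    @property
    def n_informative(self) -> int:
        return int(self.informative.sum())

    def minor_dosage(self, genotypes: GenotypeMatrix) -> np.ndarray:
        """Genotype matrix re-oriented to count minor alleles (NaN preserved)."""
        if not np.array_equal(genotypes.snp_ids, self.snp_ids):
            raise MaburdenError("assignment does not cover this genotype matrix")
        d = genotypes.dosage
        return np.where(self.minor_is_a1, d, 2.0 - d)

    def subset(self, snp_ids) -> "MaAssignment":
        """Restrict the assignment to the given SNP ids, in the given order."""
        pos = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            idx = np.array([pos[s] for s in snp_ids], dtype=int)
        except KeyError as exc:
            raise MaburdenError(f"no assignment for snp {exc.args[0]!r}") from exc
        return MaAssignment(self.snp_ids[idx], self.minor_allele[idx],
                            self.maf[idx], self.minor_is_a1[idx],
                            self.informative[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp_id": self.snp_ids,
                             "minor_allele": self.minor_allele,
                             "maf_control": self.maf,
                             "minor_is_a1": self.minor_is_a1,
                             "informative": self.informative})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MaAssignment":
        return cls(frame["snp_id"].to_numpy(object),
                   frame["minor_allele"].fillna("").to_numpy(object),
                   frame["maf_control"].to_numpy(float),
                   frame["minor_is_a1"].to_numpy(bool),
                   frame["informative"].to_numpy(bool))


@dataclass
class MacVector:
    """Per-subject MAC plus the count of SNPs actually used."""

    subject_ids: np.ndarray
    mac: np.ndarray      # NaN when a subject has no usable SNP
    n_used: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_ids, "mac": self.mac,
                             "n_used": self.n_used})


def assign_minor_alleles(cohort: Cohort,
                         controls_from: Phenotype | None = None) -> MaAssignment:
    """Designate each SNP's minor allele from control-cohort frequencies.

    ``controls_from`` defaults to the cohort's own phenotype; pass a pooled
    phenotype to reproduce an assignment over combined cohorts.
    """
    phen = controls_from if controls_from is not None else cohort.phenotype
    phen = phen.aligned_to(cohort.genotypes.subject_ids)
    controls = ~phen.is_case
    if not controls.any():
        raise MaburdenError("minor-allele assignment needs >=1 control")
    d = cohort.genotypes.dosage[controls]
    n_obs = (~np.isnan(d)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq_a1 = np.nansum(d, axis=0) / (2 * np.maximum(n_obs, 1))
    has_data = n_obs > 0

    minor_is_a1 = freq_a1 < 0.5
    maf = np.where(minor_is_a1, freq_a1, 1.0 - freq_a1)
    informative = has_data & (maf > 0.0) & (freq_a1 != 0.5)
    maf = np.where(has_data, maf, np.nan)

    a1 = cohort.snps["a1"].to_numpy(object)
    a2 = cohort.snps["a2"].to_numpy(object)
    minor = np.where(informative, np.where(minor_is_a1, a1, a2), "")
    return MaAssignment(cohort.genotypes.snp_ids.copy(), minor.astype(object),
                        maf, minor_is_a1, informative)


def compute_mac(genotypes: GenotypeMatrix, assignment: MaAssignment,
                denominator: str = "per_allele") -> MacVector:
    """Per-subject minor-allele content over informative, non-missing SNPs.

    ``denominator='per_allele'`` divides the minor-allele count by
    ``2 * n_used`` (default); ``'per_snp'`` divides by ``n_used``.
    """
    if denominator not in ("per_allele", "per_snp"):
        raise MaburdenError("denominator must be 'per_allele' or 'per_snp'")
    d = assignment.minor_dosage(genotypes)[:, assignment.informative]
    n_used = (~np.isnan(d)).sum(axis=1)
    num = np.nansum(d, axis=1)
    scale = 2.0 if denominator == "per_allele" else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        mac = np.where(n_used > 0, num / (scale * np.maximum(n_used, 1)), np.nan)
    return MacVector(genotypes.subject_ids.copy(), mac, n_used)


# ---------------------------------------------------------------------------
# two-group comparisons (means, variances, proportions)
# ---------------------------------------------------------------------------

def two_sample_z(values_a, values_b):
    """Two-tailed z-test for a difference in means with unbiased variances.

    Returns ``(z, p, (mean_a, mean_b), (sem_a, sem_b))``.  With zero variance
    in both groups: z = 0, p = 1 if the means agree, otherwise z = +/-inf,
    p = 0.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise MaburdenError("two_sample_z needs >=2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sem_a, sem_b = np.sqrt(va / a.size), np.sqrt(vb / b.size)
    se = np.sqrt(va / a.size + vb / b.size)
    diff = a.mean() - b.mean()
    if se == 0.0:
        z = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0.0 else 0.0
    else:
        z = diff / se
        p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p), (float(a.mean()), float(b.mean())), (float(sem_a), float(sem_b))


def f_test_variance(values_a, values_b):
    """Two-tailed F-test of variance homogeneity (larger variance on top)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise MaburdenError("f_test_variance needs >=2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise MaburdenError("both groups have zero variance")
    if va >= vb:
        num, den, dfn, dfd = va, vb, a.size - 1, b.size - 1
    else:
        num, den, dfn, dfd = vb, va, b.size - 1, a.size - 1
    if den == 0.0:
        return float("inf"), 0.0
    f = num / den
    p = min(1.0, 2.0 * stats.f.sf(f, dfn, dfd))
    return float(f), float(p)


def chi2_two_proportions(x1: int, n1: int, x2: int, n2: int):
    """Pearson chi-square (1 df, no continuity correction) comparing two
    sample proportions x1/n1 vs x2/n2 via the implied 2x2 table."""
    for x, n in ((x1, n1), (x2, n2)):
        if not (0 <= x <= n) or n <= 0:
            raise MaburdenError("need 0 <= x <= n and n > 0 for both groups")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    obs = np.array([[x1, n1 - x1], [x2, n2 - x2]], float)
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))
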