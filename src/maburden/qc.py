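"""SNP quality control: Hardy-Weinberg, missingness and MAF filters.

The default thresholds mirror common GWAS practice: drop SNPs with a
Hardy-Weinberg goodness-of-fit P < 0.01 (computed in controls), with more
than 5% missing genotypes, or with minor allele frequency below 0.01.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .containers import Cohort, MaburdenError

HWE_SAMPLES = ("controls_only", "all")


@dataclass(frozen=True)
class QcConfig:
    hwe_p_min: float = 0.01
    max_missing_rate: float = 0.05
    maf_min: float = 0.01
    hwe_sample: str = "controls_only"

    def __post_init__(self) -> None:
        for name in ("hwe_p_min", "max_missing_rate", "maf_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise MaburdenError(f"{name}={v} must lie in (0, 1)")
        if self.hwe_sample not in HWE_SAMPLES:
            raise MaburdenError(f"hwe_sample must be one of {HWE_SAMPLES}")


@dataclass
class QcReport:
    """Per-rule removal bookkeeping; removed + retained = input count."""

    n_input: int
    n_retained: int
    removed_by_rule: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    def counts(self) -> dict[str, int]:
        return {rule: len(ids) for rule, ids in self.removed_by_rule.items()}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"n_input": self.n_input, "n_retained": self.n_retained,
                   "n_removed": self.n_removed,
                   "removed_by_rule": {k: sorted(v) for k, v in
                                       self.removed_by_rule.items()}}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def hwe_test(n_hom_a1, n_het, n_hom_a2):
    """Two-sided Pearson 1-df chi-square test for Hardy-Weinberg proportions.

    Expected counts are (n p^2, 2 n p q, n q^2) with the allele frequency
    estimated from the sample.  Monomorphic SNPs return P = 1 (no departure
    assessable).  Accepts scalars or equal-length arrays; returns matching
    shape.
    """
    n11 = np.asarray(n_hom_a1, dtype=float)
    n12 = np.asarray(n_het, dtype=float)
    n22 = np.asarray(n_hom_a2, dtype=float)
    if (n11 < 0).any() or (n12 < 0).any() or (n22 < 0).any():
        raise MaburdenError("genotype counts must be non-negative")
    n = n11 + n12 + n22
    if (n <= 0).any():
        raise MaburdenError("total genotype count must be positive")
    p = (2 * n11 + n12) / (2 * n)
    q = 1 - p
    mono = (p == 0) | (q == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e11, e12, e22 = n * p**2, 2 * n * p * q, n * q**2
        chi2 = ((n11 - e11) ** 2 / e11 + (n12 - e12) ** 2 / e12
                + (n22 - e22) ** 2 / e22)
    chi2 = np.where(mono, 0.0, chi2)
    pval = np.where(mono, 1.0, stats.chi2.sf(chi2, df=1))
    if np.ndim(n_hom_a1) == 0:
        return float(pval)
    return pval


def hwe_exact_test(n_hom_a1, n_het, n_hom_a2) -> float:
    """Exact mid-less test of HWE (sum of heterozygote-count probabilities
    no larger than the observed one); offered as an alternative to the
    chi-square contract for small samples."""
    n11, n12, n22 = int(n_hom_a1), int(n_het), int(n_hom_a2)
    n = n11 + n12 + n22
    n_a = 2 * n11 + n12  # copies of the rarer-or-not allele a1
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    n_rare = min(n_a, 2 * n - n_a)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(het = h | n, n_rare) up to a constant, via log-gamma
    from scipy.special import gammaln
    homr = (n_rare - hets) // 2
    homc = n - hets - homr
    logp = (hets * np.log(2) + gammaln(n + 1)
            - gammaln(hets + 1) - gammaln(homr + 1) - gammaln(homc + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = min(n12, n_rare)
    p_obs = prob[np.searchsorted(hets, obs)]
    return float(prob[prob <= p_obs * (1 + 1e-12)].sum())


def _genotype_counts(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP counts of (hom a1, het, hom a2) ignoring missing entries."""
    return ((dosage == 2.0).sum(axis=0), (dosage == 1.0).sum(axis=0),
            (dosage == 0.0).sum(axis=0))


def snp_qc_stats(cohort: Cohort, config: QcConfig) -> dict[str, np.ndarray]:
    """Per-SNP QC statistics: HWE p, missing rate, MAF (all and controls)."""
    d = cohort.genotypes.dosage
    controls = ~cohort.phenotype.is_case
    hwe_d = d[controls] if config.hwe_sample == "controls_only" else d
    n11, n12, n22 = _genotype_counts(hwe_d)
    total = n11 + n12 + n22
    hwe_p = np.where(total > 0, hwe_test(n11, n12, np.where(total > 0, n22, 1)), 1.0)

    miss = np.isnan(d).mean(axis=0)

    def _maf(sub: np.ndarray) -> np.ndarray:
        cnt = (~np.isnan(sub)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            f = np.nansum(sub, axis=0) / (2 * np.maximum(cnt, 1))
        f = np.where(cnt > 0, f, np.nan)
        return np.minimum(f, 1 - f)

    return {"hwe_p": np.asarray(hwe_p, float), "missing_rate": miss,
            "maf_all": _maf(d), "maf_control": _maf(d[controls])}


def apply_qc(cohort: Cohort, config: QcConfig | None = None
             ) -> tuple[Cohort, QcReport]:
    """Filter SNPs by HWE, missingness and MAF; annotate the survivors.

    The MAF filter uses the all-subjects frequency (PLINK convention); HWE
    uses the sample selected by ``config.hwe_sample``.  SNP order is
    preserved.  Raises if nothing survives.
    """
    config = config or QcConfig()
    st = snp_qc_stats(cohort, config)
    ids = cohort.snps["snp_id"].to_numpy(object)

    hwe_fail = st["hwe_p"] < config.hwe_p_min
    missing_fail = st["missing_rate"] > config.max_missing_rate
    maf_fail = ~(st["maf_all"] >= config.maf_min)  # NaN MAF fails too
    drop = hwe_fail | missing_fail | maf_fail

    report = QcReport(
        n_input=len(ids), n_retained=int((~drop).sum()),
        removed_by_rule={"hwe_fail": list(ids[hwe_fail]),
                         "missing_fail": list(ids[missing_fail]),
                         "maf_fail": list(ids[maf_fail])})
    if report.n_retained == 0:
        raise MaburdenError("no SNPs survive QC")

    keep_idx = np.flatnonzero(~drop)
    out = cohort.take_snps(keep_idx)
    out.snps = out.snps.copy()
    out.snps["maf_all"] = st["maf_all"][keep_idx]
    out.snps["maf_control"] = st["maf_control"][keep_idx]
    return out, report
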