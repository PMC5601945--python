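"""Windowed pairwise-r2 LD pruning.

r2 here is the squared Pearson correlation of genotype dosages (composite
LD; no phasing).  Pruning is a single greedy left-to-right scan per
chromosome: each still-alive SNP is compared with every later alive SNP
within the window, and for every pair exceeding the threshold the member
with the lower MAF is removed (on a MAF tie, the one at the larger
position).  Survivors therefore contain no pair within the window with
r2 above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import Cohort, MaburdenError


@dataclass(frozen=True)
class PruneConfig:
    r2_threshold: float
    window_bp: int = 200_000
    tie_rule: str = "lower_maf"  # documented; the only implemented rule

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_threshold < 1.0:
            raise MaburdenError("r2_threshold must lie in (0, 1)")
        if self.window_bp <= 0:
            raise MaburdenError("window_bp must be positive")
        if self.tie_rule != "lower_maf":
            raise MaburdenError("unknown tie_rule")


def pairwise_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation over subjects non-missing at both SNPs.

    A vector constant on the shared support yields r2 = 0 (it can never
    exceed a pruning threshold).
    """
    a = np.asarray(dosages_a, float)
    b = np.asarray(dosages_b, float)
    if a.shape != b.shape:
        raise MaburdenError("dosage vectors must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        raise MaburdenError("need >=2 subjects non-missing at both SNPs")
    a, b = a[ok], b[ok]
    da, db = a - a.mean(), b - b.mean()
    va, vb = (da * da).sum(), (db * db).sum()
    if va == 0.0 or vb == 0.0:
        return 0.0
    r = (da * db).sum() / np.sqrt(va * vb)
    return float(min(r * r, 1.0))


def prune(cohort: Cohort, config: PruneConfig) -> list[str]:
    """Greedy LD pruning; returns surviving SNP ids in input order.

    Requires the SNP table sorted by (chromosome, position) — raises rather
    than sorting silently.  The tie-rule MAF is the ``maf_control`` column
    when present, else ``maf_all``, else computed from the matrix.
    """
    snps = cohort.snps
    chrom = snps["chrom"].to_numpy(int)
    pos = snps["pos"].to_numpy(int)
    order = np.lexsort((pos, chrom))
    if not np.array_equal(order, np.arange(len(pos))):
        raise MaburdenError("SNP table must be sorted by (chrom, pos) before pruning")

    if "maf_control" in snps.columns:
        maf = snps["maf_control"].to_numpy(float)
    elif "maf_all" in snps.columns:
        maf = snps["maf_all"].to_numpy(float)
    else:
        d = cohort.genotypes.dosage
        cnt = (~np.isnan(d)).sum(axis=0)
        f = np.nansum(d, axis=0) / (2 * np.maximum(cnt, 1))
        maf = np.minimum(f, 1 - f)
    maf = np.where(np.isnan(maf), 0.0, maf)

    d = cohort.genotypes.dosage
    # precompute centred, nan-masked columns for fast pair correlations
    mask = ~np.isnan(d)
    filled = np.where(mask, d, 0.0)

    alive = np.ones(len(pos), dtype=bool)
    m = len(pos)
    for i in range(m):
        if not alive[i]:
            continue
        j = i + 1
        while j < m and chrom[j] == chrom[i] and pos[j] - pos[i] <= config.window_bp:
            if alive[j]:
                r2 = _masked_r2(filled[:, i], mask[:, i], filled[:, j], mask[:, j])
                if r2 > config.r2_threshold:
                    if maf[i] < maf[j]:
                        alive[i] = False
                        break  # anchor removed; later pairs handled by j's turn
                    alive[j] = False
            j += 1
    return list(cohort.genotypes.snp_ids[alive])


def _masked_r2(a_filled, a_mask, b_filled, b_mask) -> float:
    ok = a_mask & b_mask
    n = ok.sum()
    if n < 2:
        return 0.0
    a = a_filled[ok]
    b = b_filled[ok]
    da, db = a - a.mean(), b - b.mean()
    va, vb = (da * da).sum(), (db * db).sum()
    if va == 0.0 or vb == 0.0:
        return 0.0
    r = (da * db).sum() / np.sqrt(va * vb)
    return min(r * r, 1.0)
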