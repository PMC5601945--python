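"""Per-SNP logistic association and wGRS / PRS score computation.

Each SNP is fitted separately: a maximum-likelihood logistic regression of
case status on minor-allele dosage {0, 1, 2} with an intercept.  The fitted
log-odds coefficient ``beta`` (and ``OR = exp(beta)``) weight the scores:

* ``wGRS_i = sum_j w_ij * beta_j`` with ``w = 1`` for homozygous-minor,
  ``0.5`` for heterozygous and ``0`` for homozygous-major (i.e. dosage/2);
* ``PRS_i = sum_j d_ij * log10(OR_j)`` with ``d`` the minor-allele dosage.

A missing genotype contributes 0 to either score and decrements the
per-subject count of SNPs used, which downstream models carry as a
covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .alleles import MaAssignment
from .containers import GenotypeMatrix, MaburdenError, Phenotype

_MAX_ABS_BETA = 30.0  # beyond this the fit is treated as separated


@dataclass
class SnpWeights:
    """Per-SNP logistic weights estimated on a training cohort."""

    table: pd.DataFrame  # snp_id, minor_allele, beta, se, p, odds_ratio, n, usable

    def __post_init__(self) -> None:
        required = {"snp_id", "minor_allele", "beta", "se", "p",
                    "odds_ratio", "n", "usable"}
        missing = required - set(self.table.columns)
        if missing:
            raise MaburdenError(f"SnpWeights table lacks columns {sorted(missing)}")

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy(object)

    def usable_ids(self) -> np.ndarray:
        return self.table.loc[self.table["usable"], "snp_id"].to_numpy(object)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "SnpWeights":
        return cls(pd.read_csv(path, sep="\t", dtype={"snp_id": str}))


@dataclass
class ScoreVector:
    """Per-subject genetic risk score and the number of SNPs used."""

    subject_ids: np.ndarray
    score: np.ndarray
    n_snps_used: np.ndarray
    score_type: str  # "wgrs" or "prs"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_ids,
                             "score": self.score,
                             "n_snps_used": self.n_snps_used})


def _logistic_newton(y: np.ndarray, D: np.ndarray, mask: np.ndarray,
                     tol: float = 1e-8, max_iter: int = 50):
    """Vectorised per-column Newton fit of ``logit P(y=1) = a + b * D``.

    ``D`` is (subjects x SNPs) with missing entries zero-filled and excluded
    via ``mask``.  Returns (a, b, se_b, converged) arrays.
    """
    n_sub, m = D.shape
    yc = y[:, None]
    ybar = y.mean()
    a = np.full(m, np.log(ybar / (1 - ybar)) if 0 < ybar < 1 else 0.0)
    b = np.zeros(m)
    active = np.ones(m, dtype=bool)
    converged = np.zeros(m, dtype=bool)
    se = np.full(m, np.nan)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Da = D[:, idx]
        Ma = mask[:, idx]
        eta = np.clip(a[idx][None, :] + b[idx][None, :] * Da, -35, 35)
        mu = expit(eta)
        w = mu * (1 - mu) * Ma
        resid = (yc - mu) * Ma
        ga = resid.sum(axis=0)
        gb = (Da * resid).sum(axis=0)
        s0 = w.sum(axis=0)
        s1 = (w * Da).sum(axis=0)
        s2 = (w * Da * Da).sum(axis=0)
        det = s0 * s2 - s1 * s1
        bad = det <= 1e-12
        det = np.where(bad, 1.0, det)
        da = (s2 * ga - s1 * gb) / det
        db = (s0 * gb - s1 * ga) / det
        da[bad] = 0.0
        db[bad] = 0.0
        a[idx] += da
        b[idx] += db
        done = (np.maximum(np.abs(da), np.abs(db))
                < tol * (1.0 + np.abs(a[idx]) + np.abs(b[idx])))
        done |= bad  # singular information: stop iterating, flag later
        newly = idx[done & ~bad]
        converged[newly] = True
        se[idx[done]] = np.sqrt(np.where(det[done] > 0, s0[done] / det[done], np.nan))
        active[idx[done]] = False
    # leftover active columns: final se estimate, not converged
    if active.any():
        idx = np.flatnonzero(active)
        Da, Ma = D[:, idx], mask[:, idx]
        eta = np.clip(a[idx][None, :] + b[idx][None, :] * Da, -35, 35)
        mu = expit(eta)
        w = mu * (1 - mu) * Ma
        s0 = w.sum(axis=0)
        s1 = (w * Da).sum(axis=0)
        s2 = (w * Da * Da).sum(axis=0)
        det = s0 * s2 - s1 * s1
        se[idx] = np.sqrt(np.where(det > 0, s0 / det, np.nan))
    return a, b, se, converged


def fit_weights(genotypes: GenotypeMatrix, assignment: MaAssignment,
                phenotype: Phenotype, tol: float = 1e-8,
                max_iter: int = 50) -> SnpWeights:
    """Fit the univariate logistic model at every informative SNP.

    SNPs with constant dosage, a non-convergent fit or apparent complete
    separation are flagged ``usable=False`` and excluded from models.
    """
    phen = phenotype.aligned_to(genotypes.subject_ids)
    if phen.n_cases == 0 or phen.n_controls == 0:
        raise MaburdenError("fit_weights needs both cases and controls")
    y = phen.status.astype(float)
    D_full = assignment.minor_dosage(genotypes)
    info_idx = np.flatnonzero(assignment.informative)
    D = D_full[:, info_idx]
    mask = ~np.isnan(D)
    Df = np.where(mask, D, 0.0)

    n_obs = mask.sum(axis=0)
    mean = Df.sum(axis=0) / np.maximum(n_obs, 1)
    var = (mask * (Df - mean[None, :]) ** 2).sum(axis=0) / np.maximum(n_obs, 1)
    constant = (var <= 0) | (n_obs < 2)
    # a SNP also needs both classes observed at non-missing entries
    has_case = (mask & (y[:, None] == 1)).any(axis=0)
    has_ctrl = (mask & (y[:, None] == 0)).any(axis=0)
    fit_ok = ~constant & has_case & has_ctrl

    a = np.full(info_idx.size, np.nan)
    b = np.full(info_idx.size, np.nan)
    se = np.full(info_idx.size, np.nan)
    conv = np.zeros(info_idx.size, dtype=bool)
    if fit_ok.any():
        cols = np.flatnonzero(fit_ok)
        a_f, b_f, se_f, conv_f = _logistic_newton(y, Df[:, cols], mask[:, cols],
                                                  tol=tol, max_iter=max_iter)
        a[cols], b[cols], se[cols], conv[cols] = a_f, b_f, se_f, conv_f

    separated = np.abs(b) > _MAX_ABS_BETA
    usable = fit_ok & conv & ~separated & np.isfinite(se)
    with np.errstate(invalid="ignore", divide="ignore"):
        zstat = b / se
        pval = 2.0 * stats.norm.sf(np.abs(zstat))

    table = pd.DataFrame({
        "snp_id": genotypes.snp_ids[info_idx],
        "minor_allele": assignment.minor_allele[info_idx],
        "beta": b, "se": se, "p": pval,
        "odds_ratio": np.exp(b),
        "n": n_obs, "usable": usable,
    })
    return SnpWeights(table)


def fit_snp_logistic(dosage, phenotype: Phenotype | np.ndarray,
                     tol: float = 1e-8, max_iter: int = 50):
    """Single-SNP logistic fit; returns ``(beta, se, p, odds_ratio)``.

    Raises on constant dosage; complete separation surfaces as a
    non-finite/huge beta flagged by the caller via :func:`fit_weights`.
    """
    y = phenotype.status.astype(float) if isinstance(phenotype, Phenotype) \
        else np.asarray(phenotype, float)
    d = np.asarray(dosage, float)
    ok = ~np.isnan(d)
    d, y = d[ok], y[ok]
    if d.size == 0 or y.min() == y.max():
        raise MaburdenError("need >=1 case and >=1 control with non-missing dosage")
    if d.min() == d.max():
        raise MaburdenError("constant dosage")
    D = d[:, None]
    mask = np.ones_like(D, dtype=bool)
    _, b, se, conv = _logistic_newton(y, D, mask, tol=tol, max_iter=max_iter)
    beta, se_b = float(b[0]), float(se[0])
    if not conv[0] or abs(beta) > _MAX_ABS_BETA:
        raise MaburdenError("logistic fit did not converge (separation?)")
    p = 2.0 * stats.norm.sf(abs(beta / se_b))
    return beta, se_b, float(p), float(np.exp(beta))


def _score(genotypes: GenotypeMatrix, assignment: MaAssignment,
           weights: SnpWeights, snp_subset, per_snp_weight,
           score_type: str) -> ScoreVector:
    subset = list(snp_subset)
    if not subset:
        raise MaburdenError("empty SNP subset")
    wtab = weights.table.set_index("snp_id")
    missing = [s for s in subset if s not in wtab.index]
    if missing:
        raise MaburdenError(f"subset SNPs without weights: {missing[:5]}")
    sub_w = wtab.loc[subset]
    if not sub_w["usable"].all():
        raise MaburdenError("subset contains SNPs flagged unusable")
    idx = genotypes.snp_indexer(subset)
    D = assignment.minor_dosage(genotypes)[:, idx]
    mask = ~np.isnan(D)
    contrib = per_snp_weight(np.where(mask, D, 0.0), sub_w)
    score = (contrib * mask).sum(axis=1)
    n_used = mask.sum(axis=1)
    return ScoreVector(genotypes.subject_ids.copy(), score, n_used, score_type)


def compute_wgrs(genotypes: GenotypeMatrix, assignment: MaAssignment,
                 weights: SnpWeights, snp_subset) -> ScoreVector:
    """Weighted genetic risk score: (dosage/2) x beta summed over the subset."""
    return _score(genotypes, assignment, weights, snp_subset,
                  lambda D, w: (D / 2.0) * w["beta"].to_numpy()[None, :],
                  "wgrs")


def compute_prs(genotypes: GenotypeMatrix, assignment: MaAssignment,
                weights: SnpWeights, snp_subset) -> ScoreVector:
    """Polygenic risk score: dosage x log10(OR) summed over the subset."""
    return _score(genotypes, assignment, weights, snp_subset,
                  lambda D, w: D * np.log10(w["odds_ratio"].to_numpy())[None, :],
                  "prs")
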