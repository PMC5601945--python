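"""Discrimination and goodness-of-fit metrics for case-control scores.

* AUC in the rank (Mann-Whitney) form, ties counted 1/2, with a DeLong
  95% confidence interval;
* TPR at 100% specificity: the fraction of cases scoring strictly above the
  maximum control score, with a Clopper-Pearson interval;
* Nagelkerke delta-R2: the Nagelkerke pseudo-R2 of a logistic model with the
  score plus the SNPs-used covariate, minus the covariate-only model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import MaburdenError


@dataclass
class EvalResult:
    auc: float
    auc_ci: tuple[float, float]
    tpr: float
    tpr_ci: tuple[float, float]
    nagelkerke_delta_r2: float | None
    n_cases: int
    n_controls: int
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"auc": self.auc, "auc_lo": self.auc_ci[0], "auc_hi": self.auc_ci[1],
                "tpr": self.tpr, "tpr_lo": self.tpr_ci[0], "tpr_hi": self.tpr_ci[1],
                "delta_r2": self.nagelkerke_delta_r2,
                "n_cases": self.n_cases, "n_controls": self.n_controls}


def _split(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise MaburdenError("scores and labels must have equal length")
    cases = s[y == 1]
    controls = s[y == 0]
    if cases.size == 0 or controls.size == 0:
        raise MaburdenError("need >=1 case and >=1 control")
    return cases, controls


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auc(scores, labels, alpha: float = 0.05):
    """Rank-based AUC with a DeLong confidence interval.

    Returns ``(auc, (lo, hi))``.  Degenerate score vectors (all values equal,
    or a single case/control) collapse the CI to the point estimate.
    """
    cases, controls = _split(scores, labels)
    m, n = cases.size, controls.size
    all_r = _midranks(np.concatenate([cases, controls]))
    case_r = _midranks(cases)
    ctrl_r = _midranks(controls)
    a = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (all_r[:m] - case_r) / n          # per-case
    v01 = 1.0 - (all_r[m:] - ctrl_r) / m    # per-control
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    if var <= 0:
        return float(a), (float(a), float(a))
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return float(a), (float(max(0.0, a - half)), float(min(1.0, a + half)))


def tpr_at_full_specificity(scores, labels, alpha: float = 0.05):
    """Fraction of cases strictly above the maximum control score.

    The threshold is the largest control score, so specificity is 100% by
    construction; a case tied with that maximum is not counted.  The CI is
    Clopper-Pearson on the case count.
    """
    cases, controls = _split(scores, labels)
    threshold = controls.max()
    k = int((cases > threshold).sum())
    m = cases.size
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, m - k + 1))
    hi = 1.0 if k == m else float(stats.beta.ppf(1 - alpha / 2, k + 1, m - k))
    return k / m, (lo, hi)


def _logit_loglik(X: np.ndarray, y: np.ndarray) -> float:
    """Maximised log-likelihood of a logistic model via statsmodels."""
    import warnings

    import statsmodels.api as sm
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        for method in ("newton", "bfgs"):
            try:
                res = sm.Logit(y, X).fit(disp=0, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                continue  # singular Hessian; try the gradient method
            if res.mle_retvals.get("converged", True):
                return float(res.llf)
    raise MaburdenError("logistic likelihood did not converge")


def _nagelkerke(ll_model: float, ll_null: float, n: int) -> float:
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll_null - ll_model))
    max_cs = 1.0 - np.exp((2.0 / n) * ll_null)
    return float(cox_snell / max_cs)


def nagelkerke_delta_r2(score, n_snps_used, labels) -> float:
    """Nagelkerke R2 of (score + covariate) minus the covariate-only model.

    The covariate is the per-subject count of SNPs used in the score; a
    constant covariate column is dropped (the covariate model then reduces
    to the intercept-only model).  Tiny negative deltas from round-off are
    clipped to 0.
    """
    y = np.asarray(labels, float)
    s = np.asarray(score, float)
    c = np.asarray(n_snps_used, float)
    if not (y.shape == s.shape == c.shape):
        raise MaburdenError("score, covariate and labels must align")
    n = y.size
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise MaburdenError("labels must include both classes")
    ll0 = n * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))

    ones = np.ones((n, 1))
    cov_cols = [] if c.min() == c.max() else [(c - c.mean())[:, None]]
    score_cols = [] if s.min() == s.max() else [(s - s.mean())[:, None]]
    X_cov = np.hstack([ones] + cov_cols)
    X_full = np.hstack([ones] + cov_cols + score_cols)

    ll_cov = ll0 if X_cov.shape[1] == 1 else _logit_loglik(X_cov, y)
    ll_full = ll0 if X_full.shape[1] == 1 else _logit_loglik(X_full, y)
    delta = _nagelkerke(ll_full, ll0, n) - _nagelkerke(ll_cov, ll0, n)
    if delta < 0 and delta > -1e-9:
        delta = 0.0
    return float(delta)


def evaluate_scores(scores, n_snps_used, labels) -> EvalResult:
    """Bundle AUC, TPR at full specificity and Nagelkerke delta-R2."""
    y = np.asarray(labels)
    a, a_ci = auc(scores, y)
    t, t_ci = tpr_at_full_specificity(scores, y)
    flags = []
    try:
        dr2 = nagelkerke_delta_r2(scores, n_snps_used, y)
    except MaburdenError:
        dr2 = None
        flags.append("delta_r2_not_computed")
    return EvalResult(a, a_ci, t, t_ci, dr2,
                      int((y == 1).sum()), int((y == 0).sum()), flags)


def roc_table(scores, labels):
    """ROC coordinates (threshold, sensitivity, specificity) for export."""
    import pandas as pd
    cases, controls = _split(scores, labels)
    thresholds = np.unique(np.concatenate([cases, controls]))[::-1]
    sens = [(cases > t).mean() for t in thresholds]
    spec = [(controls <= t).mean() for t in thresholds]
    return pd.DataFrame({"threshold": thresholds, "sensitivity": sens,
                         "specificity": spec})
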