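"""wGRS / PRS model grids, external and internal cross-validation, and
best-model selection.

A *grid* crosses a SNP-filter axis with a p-value axis:

* wGRS on all QC-passing SNPs: 5 MAF cutoffs x 26 p thresholds = 130 models;
* wGRS on LD-independent SNPs: 8 r2 thresholds x 26 p = 208 models;
* PRS: (1 total + 8 LD-independent sets) x 26 p = 234 models.

Every ingredient of a model — minor-allele assignment, per-SNP logistic
weights and p-values, LD pruning — derives from the training cohort only;
validation subjects are scored with training weights and never touch any
fitting step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alleles import MaAssignment, assign_minor_alleles
from .containers import Cohort, MaburdenError
from .ld import PruneConfig, prune
from .metrics import EvalResult, auc, evaluate_scores, tpr_at_full_specificity
from .scoring import SnpWeights, fit_weights

log = logging.getLogger(__name__)

P_GRID = (1.0, 0.6, 0.5, 0.4, 0.3, 0.2, 0.19, 0.18, 0.17, 0.16, 0.15, 0.14,
          0.13, 0.12, 0.11, 0.1, 0.09, 0.08, 0.07, 0.06, 0.05, 0.04, 0.03,
          0.02, 0.01, 0.005)
MAF_CUTOFFS = (0.5, 0.4, 0.3, 0.2, 0.1)
R2_THRESHOLDS = (0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)

#: screening thresholds (min TPR, min AUC) applied before ranking,
#: by filter family
DEFAULT_SCREEN = {"total_by_maf": (0.02, 0.57), "ld_independent": (0.0278, 0.57)}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class ModelSpec:
    """One grid cell: a filter, a p threshold and the resolved SNP list."""

    score_type: str                 # "wgrs" | "prs"
    filter_kind: str                # "total_by_maf" | "ld_independent"
    p_threshold: float
    maf_cutoff: float | None = None
    r2_threshold: float | None = None
    snp_ids: tuple = ()
    n_snps: int = 0

    def __post_init__(self) -> None:
        if self.score_type not in ("wgrs", "prs"):
            raise MaburdenError("score_type must be 'wgrs' or 'prs'")
        if self.filter_kind not in ("total_by_maf", "ld_independent"):
            raise MaburdenError("unknown filter_kind")
        if (self.maf_cutoff is None) == (self.r2_threshold is None):
            raise MaburdenError("exactly one of maf_cutoff / r2_threshold must be set")

    @property
    def evaluable(self) -> bool:
        return self.n_snps > 0

    @property
    def key(self) -> tuple:
        """Deterministic lexicographic identity for tie-breaks."""
        return (self.score_type, self.filter_kind,
                -1.0 if self.maf_cutoff is None else self.maf_cutoff,
                -1.0 if self.r2_threshold is None else self.r2_threshold,
                self.p_threshold)


class TrainingFit:
    """Everything estimated on a training cohort: MA status, weights and
    (lazily, per threshold) LD-pruned SNP sets."""

    def __init__(self, cohort: Cohort):
        self.cohort = cohort
        self.assignment: MaAssignment = assign_minor_alleles(cohort)
        self.weights: SnpWeights = fit_weights(cohort.genotypes,
                                               self.assignment,
                                               cohort.phenotype)
        self._pruned: dict[float, frozenset] = {}
        # per-SNP arrays aligned to the cohort's SNP order
        n = cohort.n_snps
        self._pval = np.full(n, np.nan)
        self._usable = np.zeros(n, dtype=bool)
        pos = {s: i for i, s in enumerate(cohort.genotypes.snp_ids)}
        widx = np.array([pos[s] for s in self.weights.snp_ids], dtype=int)
        self._pval[widx] = self.weights.table["p"].to_numpy()
        self._usable[widx] = self.weights.table["usable"].to_numpy()

    def pruned(self, r2_threshold: float, window_bp: int = 200_000) -> frozenset:
        if r2_threshold not in self._pruned:
            kept = prune(self.cohort, PruneConfig(r2_threshold, window_bp))
            self._pruned[r2_threshold] = frozenset(kept)
        return self._pruned[r2_threshold]

    def cell_snp_ids(self, filter_kind: str, p_threshold: float,
                     maf_cutoff: float | None = None,
                     r2_threshold: float | None = None) -> tuple:
        """SNPs passing the cell's filter AND p < threshold, in cohort order."""
        mask = self.assignment.informative & self._usable
        with np.errstate(invalid="ignore"):
            mask &= self._pval < p_threshold
        if filter_kind == "total_by_maf":
            with np.errstate(invalid="ignore"):
                mask &= self.assignment.maf < maf_cutoff
        else:
            kept = self.pruned(r2_threshold)
            snp_ids = self.cohort.genotypes.snp_ids
            mask &= np.fromiter((s in kept for s in snp_ids), bool, len(snp_ids))
        return tuple(self.cohort.genotypes.snp_ids[mask])


def build_grid(training: TrainingFit | Cohort, score_type: str,
               filter_kind: str | None = None) -> list[ModelSpec]:
    """Construct the full model grid for one score type.

    ``filter_kind`` selects the 130-model (total_by_maf) or 208-model
    (ld_independent) wGRS family; for ``score_type='prs'`` it is ignored and
    the combined 234-model family (1 total set at MAF < 0.5 plus 8
    LD-independent sets) is built.
    """
    fit = training if isinstance(training, TrainingFit) else TrainingFit(training)
    specs: list[ModelSpec] = []

    def add(kind, p, maf=None, r2=None):
        ids = fit.cell_snp_ids(kind, p, maf_cutoff=maf, r2_threshold=r2)
        specs.append(ModelSpec(score_type, kind, p, maf_cutoff=maf,
                               r2_threshold=r2, snp_ids=ids, n_snps=len(ids)))

    if score_type == "wgrs":
        if filter_kind == "total_by_maf":
            for maf in MAF_CUTOFFS:
                for p in P_GRID:
                    add("total_by_maf", p, maf=maf)
        elif filter_kind == "ld_independent":
            for r2 in R2_THRESHOLDS:
                for p in P_GRID:
                    add("ld_independent", p, r2=r2)
        else:
            raise MaburdenError("wgrs grid needs filter_kind "
                                "'total_by_maf' or 'ld_independent'")
    elif score_type == "prs":
        for p in P_GRID:
            add("total_by_maf", p, maf=0.5)
        for r2 in R2_THRESHOLDS:
            for p in P_GRID:
                add("ld_independent", p, r2=r2)
    else:
        raise MaburdenError("score_type must be 'wgrs' or 'prs'")
    return specs


@dataclass
class GridResult:
    """One row per model: spec provenance plus its evaluation metrics."""

    frame: pd.DataFrame
    specs: list[ModelSpec]
    provenance: dict = field(default_factory=dict)
    selected: int | None = None

    def spec_of_row(self, row: int) -> ModelSpec:
        return self.specs[row]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# cohort harmonization
# ---------------------------------------------------------------------------

def harmonize_cohorts(training: Cohort, validation: Cohort
                      ) -> tuple[Cohort, Cohort, list[str]]:
    """Restrict both cohorts to shared SNPs with reconcilable alleles.

    Validation dosages are re-oriented to the training counted allele when
    the allele columns are swapped; strand (complement) flips are applied
    when unambiguous.  A/T and C/G SNPs whose alleles only match through the
    complement, and SNPs with irreconcilable alleles, are dropped and logged.
    """
    t_idx = {s: i for i, s in enumerate(training.genotypes.snp_ids)}
    v_idx = {s: i for i, s in enumerate(validation.genotypes.snp_ids)}
    shared = [s for s in training.genotypes.snp_ids if s in v_idx]

    ta1 = training.snps["a1"].to_numpy(object)
    ta2 = training.snps["a2"].to_numpy(object)
    va1 = validation.snps["a1"].to_numpy(object)
    va2 = validation.snps["a2"].to_numpy(object)

    keep_t, keep_v, flip, dropped = [], [], [], []
    for s in shared:
        i, j = t_idx[s], v_idx[s]
        pair_t = (str(ta1[i]).upper(), str(ta2[i]).upper())
        pair_v = (str(va1[j]).upper(), str(va2[j]).upper())
        ambiguous = _COMPLEMENT.get(pair_t[0]) == pair_t[1]
        if pair_v == pair_t:
            action = "same"
        elif pair_v == pair_t[::-1]:
            action = "swap"
        else:
            comp = tuple(_COMPLEMENT.get(a, "?") for a in pair_v)
            if comp == pair_t and not ambiguous:
                action = "same"
            elif comp == pair_t[::-1] and not ambiguous:
                action = "swap"
            else:
                dropped.append(s)
                continue
        keep_t.append(i)
        keep_v.append(j)
        flip.append(action == "swap")
    if dropped:
        log.info("harmonization dropped %d SNP(s): %s", len(dropped), dropped[:10])
    if not keep_t:
        raise MaburdenError("no SNPs shared between cohorts after harmonization")

    train2 = training.take_snps(np.asarray(keep_t, int))
    valid2 = validation.take_snps(np.asarray(keep_v, int))
    flip = np.asarray(flip, bool)
    if flip.any():
        d = valid2.genotypes.dosage.copy()
        d[:, flip] = 2.0 - d[:, flip]
        valid2.genotypes.dosage = d
        snps = valid2.snps.copy()
        snps.loc[flip, ["a1", "a2"]] = snps.loc[flip, ["a2", "a1"]].to_numpy()
        valid2.snps = snps
    return train2, valid2, dropped


# ---------------------------------------------------------------------------
# external cross-validation
# ---------------------------------------------------------------------------

def _evaluate_grid(fit: TrainingFit, specs: list[ModelSpec], target: Cohort,
                   compute_delta_r2: bool = True) -> pd.DataFrame:
    """Score a target cohort for every spec and collect metrics."""
    assignment = fit.assignment
    # assignment is aligned to the (harmonized) training SNP order == target order
    D = assignment.minor_dosage(target.genotypes)
    mask = ~np.isnan(D)
    Df = np.where(mask, D, 0.0)
    y = target.phenotype.status

    wtab = fit.weights.table
    pos = {s: i for i, s in enumerate(target.genotypes.snp_ids)}
    widx = np.array([pos[s] for s in wtab["snp_id"]], dtype=int)
    beta_full = np.zeros(target.n_snps)
    beta_full[widx] = wtab["beta"].to_numpy()

    rows = []
    for spec in specs:
        if not spec.evaluable:
            rows.append(_row(spec, None))
            continue
        cols = np.array([pos[s] for s in spec.snp_ids], dtype=int)
        if spec.score_type == "wgrs":
            contrib = (Df[:, cols] / 2.0) * beta_full[cols][None, :]
        else:
            contrib = Df[:, cols] * (beta_full[cols][None, :] / np.log(10.0))
        scores = (contrib * mask[:, cols]).sum(axis=1)
        n_used = mask[:, cols].sum(axis=1)
        if compute_delta_r2:
            res = evaluate_scores(scores, n_used, y)
        else:
            a, a_ci = auc(scores, y)
            t, t_ci = tpr_at_full_specificity(scores, y)
            res = EvalResult(a, a_ci, t, t_ci, None,
                             int((y == 1).sum()), int((y == 0).sum()))
        rows.append(_row(spec, res))
    return pd.DataFrame(rows)


def _row(spec: ModelSpec, res: EvalResult | None) -> dict:
    d = {"score_type": spec.score_type, "filter_kind": spec.filter_kind,
         "maf_cutoff": spec.maf_cutoff, "r2_threshold": spec.r2_threshold,
         "p_threshold": spec.p_threshold, "n_snps": spec.n_snps,
         "evaluable": spec.evaluable and res is not None}
    empty = {"auc": np.nan, "auc_lo": np.nan, "auc_hi": np.nan, "tpr": np.nan,
             "tpr_lo": np.nan, "tpr_hi": np.nan, "delta_r2": np.nan,
             "n_cases": 0, "n_controls": 0}
    if res is None:
        d.update(empty)
    else:
        rd = res.as_dict()
        rd["delta_r2"] = np.nan if rd["delta_r2"] is None else rd["delta_r2"]
        d.update(rd)
    return d


def external_cv(training: Cohort, validation: Cohort, score_type: str = "wgrs",
                filter_kind: str | None = "total_by_maf",
                compute_delta_r2: bool = True) -> GridResult:
    """Fit the grid on the training cohort, evaluate on the validation cohort.

    Subject overlap between cohorts is a hard error; SNPs are harmonized by
    id with allele reconciliation first.
    """
    overlap = set(training.genotypes.subject_ids) & set(validation.genotypes.subject_ids)
    if overlap:
        raise MaburdenError(f"subject overlap between cohorts: {sorted(overlap)[:5]}")
    train2, valid2, dropped = harmonize_cohorts(training, validation)
    fit = TrainingFit(train2)
    specs = build_grid(fit, score_type, filter_kind)
    frame = _evaluate_grid(fit, specs, valid2, compute_delta_r2=compute_delta_r2)
    prov = {"training": training.name, "validation": validation.name,
            "mode": "external_cv", "n_dropped_harmonization": len(dropped)}
    return GridResult(frame, specs, provenance=prov)


# ---------------------------------------------------------------------------
# internal 10-fold cross-validation
# ---------------------------------------------------------------------------

def make_folds(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition into near-equal folds (sizes differ by <= 1)."""
    order = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(order, n_folds)]


def internal_cv_10fold(cohort: Cohort, model_spec: ModelSpec,
                       n_repeats: int = 1, n_folds: int = 10,
                       seed: int | np.random.Generator = 0,
                       refit_per_fold: bool = True,
                       max_attempts: int = 100):
    """Repeated 10-fold cross-validation of one model specification.

    Each fold serves once as validation; minor-allele status and weights are
    refitted on the remaining folds (``refit_per_fold=False`` reuses
    whole-cohort weights, the variant that leaks validation labels, offered
    for comparison only).  The model's filter/p thresholds are re-applied on
    each training split.  Returns ``(mean_auc, mean_tpr, per_fold_frame)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = cohort.n_subjects
    if n < n_folds:
        raise MaburdenError("cohort smaller than the number of folds")
    status = cohort.phenotype.status
    whole_fit = None if refit_per_fold else TrainingFit(cohort)

    records = []
    for rep in range(n_repeats):
        folds = None
        for _ in range(max_attempts):
            cand = make_folds(n, n_folds, rng)
            if all(0 < status[f].sum() < f.size for f in cand):
                folds = cand
                break
        if folds is None:
            raise MaburdenError("could not partition with both classes per fold")
        for k, val_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), val_idx)
            val_cohort = cohort.take_subjects(val_idx)
            if refit_per_fold:
                fit = TrainingFit(cohort.take_subjects(train_idx))
                ids = fit.cell_snp_ids(model_spec.filter_kind,
                                       model_spec.p_threshold,
                                       maf_cutoff=model_spec.maf_cutoff,
                                       r2_threshold=model_spec.r2_threshold)
            else:
                fit = whole_fit
                ids = model_spec.snp_ids
            spec_k = ModelSpec(model_spec.score_type, model_spec.filter_kind,
                               model_spec.p_threshold,
                               maf_cutoff=model_spec.maf_cutoff,
                               r2_threshold=model_spec.r2_threshold,
                               snp_ids=ids, n_snps=len(ids))
            if not spec_k.evaluable:
                records.append({"repeat": rep, "fold": k, "n_snps": 0,
                                "auc": np.nan, "tpr": np.nan})
                continue
            frame = _evaluate_grid(fit, [spec_k], val_cohort,
                                   compute_delta_r2=False)
            records.append({"repeat": rep, "fold": k,
                            "n_snps": spec_k.n_snps,
                            "auc": frame.loc[0, "auc"],
                            "tpr": frame.loc[0, "tpr"]})
    per_fold = pd.DataFrame(records)
    return (float(per_fold["auc"].mean()), float(per_fold["tpr"].mean()),
            per_fold)


# ---------------------------------------------------------------------------
# best-model selection
# ---------------------------------------------------------------------------

def select_best_model(grid_result: GridResult,
                      screen="default") -> ModelSpec | None:
    """Select the best model: screen, then rank by AUC, then TPR, then
    delta-R2, then fewer SNPs, then the deterministic spec key.

    ``screen`` is ``"default"`` (the per-family (min TPR, min AUC)
    thresholds in :data:`DEFAULT_SCREEN`), ``None`` (no screen), or a
    ``(min_tpr, min_auc)`` pair applied to every row.  Metrics are compared
    after rounding to 9 decimals so numerically tied models fall through to
    the SNP-count rule.  Returns ``None`` (with a diagnostic in
    ``grid_result.provenance``) when nothing passes the screen.
    """
    df = grid_result.frame
    ok = df["evaluable"].to_numpy(bool) & df["auc"].notna().to_numpy()
    if screen == "default":
        for kind, (tpr_min, auc_min) in DEFAULT_SCREEN.items():
            fam = (df["filter_kind"] == kind).to_numpy()
            ok &= ~fam | ((df["tpr"].to_numpy() >= tpr_min)
                          & (df["auc"].to_numpy() > auc_min))
    elif screen is not None:
        tpr_min, auc_min = screen
        ok &= (df["tpr"].to_numpy() >= tpr_min) & (df["auc"].to_numpy() > auc_min)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        grid_result.provenance["selection"] = "no model passed the screen"
        grid_result.selected = None
        return None

    def rank_key(i: int):
        r = df.iloc[i]
        dr2 = -1.0 if pd.isna(r["delta_r2"]) else round(float(r["delta_r2"]), 9)
        return (-round(float(r["auc"]), 9), -round(float(r["tpr"]), 9), -dr2,
                int(r["n_snps"]), grid_result.specs[i].key)

    best = min(idx, key=rank_key)
    grid_result.selected = int(best)
    grid_result.provenance["selection"] = "ok"
    return grid_result.specs[best]
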