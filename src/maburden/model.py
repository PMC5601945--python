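"""Model/Results front-end tying the pipeline together.

:class:`MinorAlleleRiskModel` is built from a training and a validation
case-control cohort; ``fit()`` runs QC, minor-allele assignment, per-SNP
logistic weighting, the model grid with external cross-validation, and
best-model selection, returning a :class:`MinorAlleleRiskResults` with the
grid table, the selected model, the minor-allele-content comparison and a
``summary()`` in the spirit of statsmodels results objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alleles import assign_minor_alleles, compute_mac, two_sample_z
from .containers import Cohort, MaburdenError
from .grid import GridResult, ModelSpec, external_cv, internal_cv_10fold, \
    select_best_model
from .qc import QcConfig, QcReport, apply_qc


class MinorAlleleRiskModel:
    """Minor-allele burden and risk-prediction analysis of two cohorts.

    Parameters
    ----------
    training, validation : Cohort
        Disjoint case-control cohorts; all estimation uses ``training``.
    score_type : "wgrs" or "prs"
    filter_kind : "total_by_maf" or "ld_independent" (ignored for PRS)
    qc_config : QcConfig, applied to each cohort before analysis
    screen : best-model screen passed to :func:`select_best_model`
    """

    def __init__(self, training: Cohort, validation: Cohort,
                 score_type: str = "wgrs",
                 filter_kind: str = "total_by_maf",
                 qc_config: QcConfig | None = None,
                 screen="default"):
        if score_type not in ("wgrs", "prs"):
            raise MaburdenError("score_type must be 'wgrs' or 'prs'")
        self.training = training
        self.validation = validation
        self.score_type = score_type
        self.filter_kind = filter_kind
        self.qc_config = qc_config or QcConfig()
        self.screen = screen

    @classmethod
    def from_text(cls, training_dir, validation_dir, **kwargs
                  ) -> "MinorAlleleRiskModel":
        from .io import read_text
        return cls(read_text(training_dir), read_text(validation_dir), **kwargs)

    @classmethod
    def from_plink(cls, training_prefix, validation_prefix, **kwargs
                   ) -> "MinorAlleleRiskModel":
        from pathlib import Path
        from .io import read_plink
        return cls(read_plink(Path(training_prefix).with_suffix(".bed")),
                   read_plink(Path(validation_prefix).with_suffix(".bed")),
                   **kwargs)

    def fit(self, compute_delta_r2: bool = True) -> "MinorAlleleRiskResults":
        train_qc, train_report = apply_qc(self.training, self.qc_config)
        valid_qc, valid_report = apply_qc(self.validation, self.qc_config)

        grid = external_cv(train_qc, valid_qc, score_type=self.score_type,
                           filter_kind=self.filter_kind,
                           compute_delta_r2=compute_delta_r2)
        best = select_best_model(grid, screen=self.screen)

        mac_tests = {}
        for label, cohort in (("training", train_qc), ("validation", valid_qc)):
            assignment = assign_minor_alleles(cohort)
            mac = compute_mac(cohort.genotypes, assignment)
            is_case = cohort.phenotype.is_case
            z, p, means, sems = two_sample_z(mac.mac[is_case], mac.mac[~is_case])
            mac_tests[label] = {
                "mac_cases": means[0], "mac_controls": means[1],
                "sem_cases": sems[0], "sem_controls": sems[1],
                "z": z, "p": p,
                "n_cases": int(is_case.sum()), "n_controls": int((~is_case).sum()),
            }

        return MinorAlleleRiskResults(
            model=self, grid=grid, best=best, mac_tests=mac_tests,
            qc_reports={"training": train_report, "validation": valid_report},
            cohorts={"training": train_qc, "validation": valid_qc})


@dataclass
class MinorAlleleRiskResults:
    """Fitted grid, selection and burden comparison for two cohorts."""

    model: MinorAlleleRiskModel
    grid: GridResult
    best: ModelSpec | None
    mac_tests: dict
    qc_reports: dict[str, QcReport]
    cohorts: dict[str, Cohort] = field(default_factory=dict)

    @property
    def best_row(self) -> pd.Series | None:
        if self.grid.selected is None:
            return None
        return self.grid.frame.iloc[self.grid.selected]

    def internal_cv(self, n_repeats: int = 1, seed: int = 0,
                    refit_per_fold: bool = True):
        """Repeated 10-fold internal CV of the selected model on the
        training cohort; returns (mean_auc, mean_tpr, per_fold)."""
        if self.best is None:
            raise MaburdenError("no selected model to cross-validate")
        return internal_cv_10fold(self.cohorts["training"], self.best,
                                  n_repeats=n_repeats, seed=seed,
                                  refit_per_fold=refit_per_fold)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Minor-Allele Risk Prediction Results",
            "=" * 68,
            f"score type: {m.score_type:<12s} filter family: {m.filter_kind}",
            f"training:   {m.training.name} "
            f"({self.mac_tests['training']['n_cases']} cases / "
            f"{self.mac_tests['training']['n_controls']} controls, "
            f"{self.qc_reports['training'].n_retained} SNPs after QC)",
            f"validation: {m.validation.name} "
            f"({self.mac_tests['validation']['n_cases']} cases / "
            f"{self.mac_tests['validation']['n_controls']} controls, "
            f"{self.qc_reports['validation'].n_retained} SNPs after QC)",
            "-" * 68,
            "Minor allele content (cases vs controls)",
        ]
        for label, t in self.mac_tests.items():
            lines.append(
                f"  {label:<10s} MAC {t['mac_cases']:.5f} +/- {t['sem_cases']:.2e}"
                f" vs {t['mac_controls']:.5f} +/- {t['sem_controls']:.2e}"
                f"   z = {t['z']:+.3f}, P = {t['p']:.3g}")
        lines.append("-" * 68)
        n_models = len(self.grid.frame)
        n_eval = int(self.grid.frame["evaluable"].sum())
        lines.append(f"model grid: {n_models} models ({n_eval} evaluable), "
                     "externally cross-validated")
        row = self.best_row
        if row is None:
            lines.append("selected model: none "
                         f"({self.grid.provenance.get('selection')})")
        else:
            filt = (f"MAF < {row['maf_cutoff']}" if row["filter_kind"] == "total_by_maf"
                    else f"r2 <= {row['r2_threshold']}")
            lines.append(f"selected model: {filt}, P < {row['p_threshold']}, "
                         f"{int(row['n_snps'])} SNPs")
            lines.append(f"  AUC {row['auc']:.4f} "
                         f"(95% CI {row['auc_lo']:.4f}-{row['auc_hi']:.4f})")
            lines.append(f"  TPR at 100% specificity {100 * row['tpr']:.2f}% "
                         f"(95% CI {100 * row['tpr_lo']:.3f}-{100 * row['tpr_hi']:.3f}%)")
            if np.isfinite(row["delta_r2"]):
                lines.append(f"  Nagelkerke delta-R2 {100 * row['delta_r2']:.2f}%")
        lines.append("=" * 68)
        return "\n".join(lines)
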