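# maburden

Minor-allele burden statistics and cross-validated genetic risk-score
prediction for case-control SNP cohorts.

## The problem

Complex diseases such as schizophrenia are driven by very large numbers of
common variants of small effect. One way to summarise this polygenic load
is to ask how many **minor alleles** (MAs — the allele with control-cohort
frequency < 0.5) a person carries. `maburden` implements this analysis end
to end for PLINK-format (or plain-text) genotype data:

* **QC** — Hardy–Weinberg (P < 0.01 in controls), missingness (> 5%) and
  MAF (< 0.01) filters on autosomal biallelic SNPs;
* **MAC** (minor-allele content) — the per-subject fraction of carried
  alleles that are minor, `MAC_i = Σ_j d_ij / (2 n_i)` over informative,
  non-missing SNPs, compared between cases and controls with a two-tailed
  z-test (plus F-test and two-proportion χ² helpers);
* **LD pruning** — greedy pairwise-r² pruning within a 200 kb window at
  thresholds r² ∈ {0.8, …, 0.1};
* **wGRS** — weighted genetic risk score `Σ_j w_ij β_j`, where β_j is the
  per-SNP logistic regression coefficient fitted on a *training* cohort and
  w = 1 / 0.5 / 0 for homozygous-minor / heterozygous / homozygous-major;
* **PRS** — `Σ_j d_ij log10(OR_j)` over minor-allele dosages, for
  comparison;
* **model grids** — 130 wGRS models (5 MAF cutoffs × 26 p-value
  thresholds), 208 wGRS models (8 r² thresholds × 26 p), and 234 PRS models
  (9 SNP sets × 26 p), evaluated by **external cross-validation** (train on
  one cohort, validate on an independent one) and repeated **10-fold
  internal cross-validation**, with AUC (DeLong 95% CI), TPR at 100%
  specificity (the fraction of cases scoring strictly above every control;
  Clopper–Pearson CI) and Nagelkerke ΔR² (score + SNP-count covariate vs
  covariate only);
* **best-model selection** — screen on TPR/AUC, then rank by AUC, TPR,
  ΔR², and prefer fewer SNPs on ties;
* **synthetic cohorts** — a liability-threshold generator with blockwise
  LD, realistic MAF spectra, missing genotypes, and a tunable probability
  that risk alleles are minor alleles, providing ground truth for every
  stage.

Real psychiatric-genetics cohorts are controlled-access, so the package
ships a first-class simulator instead of data; all statistical machinery is
exercised and validated on simulated cohorts.

## Worked example

```python
import maburden as mb

cfg = mb.SimConfig(n_cases=300, n_controls=300, m_snps=2000, seed=42)
(train, valid), truth = mb.simulate_cohorts(cfg)

model = mb.MinorAlleleRiskModel(train, valid, score_type="wgrs",
                                filter_kind="total_by_maf", screen=None)
results = model.fit()
print(results.summary())
```

prints

```
Minor-Allele Risk Prediction Results
====================================================================
score type: wgrs         filter family: total_by_maf
training:   cohort1 (300 cases / 300 controls, 1980 SNPs after QC)
validation: cohort2 (300 cases / 300 controls, 1969 SNPs after QC)
--------------------------------------------------------------------
Minor allele content (cases vs controls)
  training   MAC 0.26064 +/- 1.08e-03 vs 0.25441 +/- 9.82e-04   z = +4.264, P = 2.01e-05
  validation MAC 0.26075 +/- 9.75e-04 vs 0.25525 +/- 9.86e-04   z = +3.963, P = 7.4e-05
--------------------------------------------------------------------
model grid: 130 models (130 evaluable), externally cross-validated
selected model: MAF < 0.5, P < 0.03, 181 SNPs
  AUC 0.7641 (95% CI 0.7265-0.8018)
  TPR at 100% specificity 2.00% (95% CI 0.737-4.302%)
  Nagelkerke delta-R2 26.14%
====================================================================
```

Reading this output: cases carry a visibly higher minor-allele content than
controls in both cohorts (MAC 0.2606 vs 0.2544 in training, z = +4.26) —
the burden signal planted by the generator (`minor_risk_prob = 0.7` of
causal risk alleles are minor). The grid search over 130 (MAF cutoff ×
p-threshold) cells selects a 181-SNP model whose scores, fitted only on the
training cohort, discriminate cases from controls in the held-out cohort
with AUC 0.76; 2% of validation cases score above *every* validation
control. Internal 10-fold cross-validation of the selected model
(`results.internal_cv(seed=0)`) gives mean AUC 0.7642.

The same pipeline is scriptable from the shell:

```bash
maburden simulate --seed 5 --out data
maburden qc --in data/cohort1 --out qc1
maburden assign-ma --in qc1 --out ma.tsv
maburden mac --in qc1 --ma ma.tsv --out mac.tsv
maburden prune --in qc1 --r2 0.5 --out kept.txt
maburden grid --train qc1 --valid qc2 --out grid.tsv
maburden select --grid grid.tsv --out best.json
```

Every subcommand is deterministic given `--seed` and its inputs.

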