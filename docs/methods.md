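# Methods

This note documents the statistical contracts, the generative model behind
the synthetic cohorts, and the design choices made where the underlying
procedure admits more than one reasonable reading.

## Genotype model and conventions

Genotypes are autosomal, biallelic dosages of a per-SNP *counted* allele —
by convention the first allele column (`a1`) of the SNP table — taking
values {0, 1, 2} or missing (NaN). Coordinates are 1-based base pairs.
PLINK 1 binary files are read and written directly (SNP-major v1.00, 2-bit
codes, A1 counted); the text dialect is three TSV files (genotypes, SNP
table, phenotypes). Missing genotypes are never imputed at the I/O or QC
layer; each downstream statistic defines its own missing-data rule.

## Quality control

Per SNP, three removal rules, applied as a union:

* **HWE**: 1-df Pearson goodness-of-fit against (np², 2npq, nq²) with p
  estimated from the sample; default threshold P < 0.01. The test runs in
  controls only by default (`hwe_sample`), the standard case-control
  practice, since disease association itself distorts HWE in cases; an
  exact test is available as an alternative for small counts. Monomorphic
  SNPs return P = 1 (no departure assessable).
* **Missingness**: fraction of missing genotypes > 0.05. The rule is read
  as *excluding* high-missingness SNPs (the filter exists to drop
  poor-quality assays).
* **MAF**: all-subjects minor allele frequency < 0.01 (the PLINK
  convention for the QC frequency; minor-allele *assignment*, below, is a
  separate control-only computation). Rare variants are removed because
  genotyping artefacts concentrate there.

QC is idempotent and monotone in each threshold; the report accounts for
every removal, with a SNP allowed to fail several rules but removed once.

## Minor-allele assignment and MAC

The minor allele of a SNP is the allele with frequency < 0.5 among
non-missing **control** genotypes. A SNP is *non-informative* — and
excluded from every burden statistic — when that frequency is exactly 0.5
(the strict `MAF < 0.5` cutoff), when the SNP is monomorphic, or when no
control genotype is observed.

Per-subject minor-allele content is

```
MAC_i = (Σ_j minor-allele dosage at SNP j) / (2 · n_i)
```

over informative SNPs with a non-missing genotype for subject i (`n_i` of
them). The per-allele denominator (2·n) puts MAC on the frequency scale —
its expectation under Hardy–Weinberg equals the mean control MAF of the
panel, which is how reported MAC magnitudes (~0.2) should be read. A
literal per-SNP denominator (`/ n_i`) is available as a configuration
switch. Group comparisons use the two-tailed z-test with unbiased
variances, the variance-ratio F-test (larger variance on top, two-tailed),
and the 1-df Pearson χ² for two proportions without continuity correction.

## LD pruning

r² is the squared Pearson correlation of genotype dosages over subjects
non-missing at both SNPs (composite LD; genotype data carry no phase). A
vector constant on the shared support gets r² = 0, since it cannot exceed
any threshold. Pruning is a single greedy left-to-right scan per
chromosome with a fixed 200 kb window anchored at each surviving SNP: for
every pair within the window exceeding the threshold, the lower-MAF member
is removed (on a MAF tie, the one at the larger position). This rule is
deterministic, independent of subject ordering, and guarantees that no
surviving pair within any window exceeds the threshold. The SNP table must
arrive sorted by (chromosome, position); an unsorted table is an error
rather than a silent sort. Step-and-slide semantics of external pruning
tools are intentionally not emulated; the fixed-window greedy scan *is*
this package's definition of an LD-independent set.

## Per-SNP weights and scores

Each informative SNP gets a univariate maximum-likelihood logistic
regression of case status on minor-allele dosage {0, 1, 2} with intercept
(Newton iterations, relative tolerance 1e-8, cap 50; vectorised across
SNPs). Non-convergent or separated fits (|β| > 30 or a singular
information matrix) are flagged unusable and excluded from models rather
than clipped. Wald p-values and OR = exp(β) accompany each β.

* **wGRS**: Σ_j w_ij β_j with w = dosage/2 ∈ {0, 0.5, 1} — the
  1×/0.5×/0× weighting of homozygous-minor/heterozygous/homozygous-major
  genotypes.
* **PRS**: Σ_j d_ij log10(OR_j) with d the allele count {0, 1, 2}, the
  classic polygenic-scoring convention.

A missing genotype contributes 0 and decrements the per-subject count of
SNPs used; that count travels with the scores as the covariate of the
Nagelkerke computation. Scores are reported raw (no centering), so their
absolute level is not comparable across weight sets — only case-control
contrasts and ranks are interpreted.

## Evaluation metrics

* **AUC**: Mann–Whitney rank form with ties at 1/2; 95% CI by DeLong's
  structural-components variance (normal quantiles, clipped to [0, 1]).
* **TPR at 100% specificity**: threshold = the maximum control score; TPR
  = fraction of cases *strictly* above it (a case tied with the best
  control does not count). CI by Clopper–Pearson on the case count, chosen
  for exact coverage at the tiny proportions this statistic produces.
* **Nagelkerke ΔR²**: R²_N = [1 − exp((2/n)(ℓ₀ − ℓ))]/[1 − exp((2/n)ℓ₀)],
  reported as R²_N(score + SNP-count covariate) − R²_N(covariate only).
  The nested fits use statsmodels' Logit (Newton, BFGS fallback); a
  constant covariate column is dropped, and deltas negative by < 1e-9 from
  round-off are clipped to 0.

## Model grids and cross-validation

Three families: wGRS on all QC-passing SNPs (MAF cutoffs 0.5/0.4/0.3/0.2/
0.1 × 26 p-value thresholds = 130 models), wGRS on LD-independent sets
(r² 0.8…0.1 × 26 = 208), and PRS (1 total + 8 LD-independent sets × 26 =
234). The p grid is {1, 0.6, 0.5, 0.4, 0.3, 0.2, 0.19, …, 0.01, 0.005};
cells are nested in p within a filter. A cell's SNP list is the training
cohort's informative, usable-weight SNPs passing the filter AND p <
threshold; an empty cell is retained but marked unevaluable.

**External CV** fits everything — minor-allele status, weights, p-values,
pruning — on the training cohort only and scores the validation cohort
with those frozen ingredients. Cohorts are first harmonised: SNPs
intersected by id, validation dosages re-oriented where allele columns are
swapped, unambiguous strand flips applied, and A/T / C/G SNPs whose
alleles match only through the complement dropped (their orientation is
undecidable). Subject overlap between cohorts is a hard error.

**Internal CV** partitions one cohort into 10 near-equal folds by seeded
shuffle (sizes differ by ≤ 1, e.g. 2,154 → 4×216 + 6×215); each fold
serves once as validation while minor-allele status and weights are
*refitted on the remaining folds* and the cell's thresholds re-applied.
Not refitting would leak validation labels through the whole-cohort
weights; that leaky variant is available behind a flag purely for
comparison. A partition leaving a fold without both classes is resampled
(up to 100 attempts).

**Selection**: models are first screened (defaults: TPR ≥ 2% and
AUC > 0.57 for total-SNP models; TPR ≥ 2.78% and AUC > 0.57 for
LD-independent models; both configurable, or no screen), then ranked by
AUC, ties broken by TPR, then ΔR², then fewer SNPs, then a lexicographic
spec key. "Ties" compare metrics rounded to 9 decimals, so differences at
numerical noise level fall through to the parsimony rule. The ordering is
one fixed, documented resolution of "largest AUC, TPR as well as ΔR²";
the grid table preserves all metrics so any other composite can be applied
post hoc.

## Synthetic cohorts

The generator emulates a pair of exchangeable case-control GWAS cohorts:

* **MAF spectrum**: per-SNP targets Uniform(0.01, 0.5), shared across
  cohorts (optional per-cohort jitter stress-tests harmonisation).
* **LD**: haplotypes are thresholded blockwise AR(1) latent Gaussians
  (block size 25 SNPs, latent ρ = 0.9 by default, giving adjacent-dosage
  r² ≈ 0.3 and a pruning gradient across the r² grid comparable to chip
  data; ρ is attenuated by dichotomisation, so latent and dosage
  correlations differ). Blocks are independent; genotype = sum of two
  independent haplotypes, so marginal HWE holds by construction. SNPs sit
  5 kb apart in contiguous blocks across the 22 autosomes.
* **Architecture**: a fraction π = 0.05 of SNPs is causal with liability
  effects |N(0, 0.15)| per risk allele; each causal SNP's risk allele is
  its minor allele with probability q (`minor_risk_prob`, default 0.7 — the
  single knob that produces minor-allele enrichment in cases; q = 0.5
  makes the burden signal vanish by symmetry).
* **Phenotype**: liability = Σ effects·(risk dosage) + N(0, 1); case iff
  liability exceeds the quantile of a 1% population prevalence (the
  lifetime risk of schizophrenia). The threshold uses the analytic mean
  and variance of the genetic score ignoring LD covariance among causal
  SNPs; case/control counts are exact by rejection sampling, so this
  approximation only perturbs the realised enrichment slightly.
* **Sampling**: because cases are rare, candidates are first drawn only at
  causal positions (the AR process restricted to a subset of positions is
  still Markov); accepted subjects then get the full panel from the exact
  AR(1) Gaussian bridge conditional on those values. The two-stage law
  equals the direct sampler's, which is kept and tested as an oracle.
  Missingness is MCAR at rate 0.01. Everything derives from a single seed
  via spawned substreams; identical seeds give byte-identical cohorts.

Default cohort sizes (500 cases + 500 controls, 5,000 SNPs, two cohorts)
are the scale at which the test suite and the acceptance script run the
end-to-end analyses; structural checks use smaller panels. What the
simulator does *not* model: recombination-map realism, ancestry structure
and admixture, genotyping batch effects, imputation dosages, sex
chromosomes. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under the stated generative
assumptions, not robustness to confounding in real cohorts — ancestry
control (e.g. PC-based outlier removal) must happen upstream.

## Numerical notes

* Logistic Newton solvers clip the linear predictor to ±35 before the
  sigmoid; the per-SNP solver declares separation at |β| > 30.
* AUC/TPR are invariant to strictly increasing score transforms; ties are
  handled by midranks (AUC) and strict inequality (TPR).
* Degenerate inputs have defined outcomes rather than exceptions where a
  value is meaningful: constant scores → AUC 0.5 with a collapsed CI;
  both-groups-zero-variance z-test → z = 0, P = 1 (equal means) or ±∞,
  P = 0; pooled proportion 0 or 1 → χ² = 0, P = 1; constant r² vectors →
  r² = 0.
* All tabular output is written with a fixed `%.10g` float format so
  reruns are byte-identical.

## Known limitations

* The wGRS β is fitted on dosage {0, 1, 2} while the score weights are
  dosage/2, so score magnitudes are on a "per allele-pair" scale; this
  reproduces the 1×/0.5×/0× weighting exactly and affects no rank-based
  metric.
* Whether PRS should weight dosage {0, 1, 2} or {0, 0.5, 1} is a genuine
  ambiguity; the allele-count convention is used and documented.
* Greedy pruning survivor counts are monotone in the r² threshold on
  realistic LD structures (and verified on simulation), but the greedy
  scan does not carry a formal monotonicity proof for adversarial inputs.
* The two-group z-test assumes large-ish groups (normal reference); at
  very small n it is anticonservative, as spreadsheet z-tests are.
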