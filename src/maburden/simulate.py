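"""Synthetic paired case-control cohorts under a liability-threshold model.

Haplotypes are drawn by thresholding a blockwise AR(1) latent Gaussian:
within each LD block the latent values of consecutive SNPs have correlation
``ld_rho`` and each SNP's threshold is the quantile of its target minor
allele frequency, so sample MAFs match their targets and genotypes (the sum
of two independent haplotypes) are in Hardy-Weinberg proportions
marginally.  Disease liability is the sum of per-SNP risk-allele effects
plus standard normal noise; a subject is a case when liability exceeds the
population-prevalence quantile.  Cases and controls are accumulated by
rejection sampling, so a low prevalence (the default, 1%, matches the
lifetime risk of schizophrenia) makes case generation the dominant cost.

The single knob that produces a minor-allele burden signal is
``minor_risk_prob``: the probability that a causal SNP's risk allele is its
minor allele.  At 0.5 risk is orientation-agnostic and the case/control MAC
difference vanishes in expectation; above 0.5 cases accumulate minor
alleles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Cohort, GenotypeMatrix, MaburdenError, Phenotype
from .ld import pairwise_r2

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    n_cases: int = 500
    n_controls: int = 500
    n_cohorts: int = 2
    m_snps: int = 5000
    maf_low: float = 0.01
    maf_high: float = 0.5
    ld_block_size: int = 25
    ld_rho: float = 0.9
    causal_fraction: float = 0.05
    effect_sd: float = 0.15
    minor_risk_prob: float = 0.7
    prevalence: float = 0.01
    missing_rate: float = 0.01
    maf_drift_sd: float = 0.0   # per-cohort jitter of target MAFs
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ld_rho < 1.0:
            raise MaburdenError("ld_rho must lie in [0, 1)")
        if not 0.0 <= self.causal_fraction <= 1.0:
            raise MaburdenError("causal_fraction must lie in [0, 1]")
        if not 0.0 <= self.minor_risk_prob <= 1.0:
            raise MaburdenError("minor_risk_prob must lie in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise MaburdenError("prevalence must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 0.5:
            raise MaburdenError("missing_rate must lie in [0, 0.5)")
        if not 0.0 < self.maf_low < self.maf_high <= 0.5:
            raise MaburdenError("need 0 < maf_low < maf_high <= 0.5")
        if self.ld_block_size <= 0 or self.m_snps <= 0:
            raise MaburdenError("m_snps and ld_block_size must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        return cls(**json.loads(text))


@dataclass
class SimTruth:
    """Ground truth: per-SNP causal structure and per-subject liabilities."""

    snps: pd.DataFrame          # snp_id, maf_target, causal, effect, risk_allele
    liabilities: dict           # cohort name -> per-subject liability array
    threshold: float


def _snp_layout(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    m = config.m_snps
    n_blocks = (m + config.ld_block_size - 1) // config.ld_block_size
    block = np.repeat(np.arange(n_blocks), config.ld_block_size)[:m]
    # contiguous runs of blocks per autosome (keeps the table sorted), 5 kb spacing
    blocks_per_chrom = max(1, (n_blocks + 21) // 22)
    chrom_of_block = np.minimum(np.arange(n_blocks) // blocks_per_chrom, 21) + 1
    chrom = chrom_of_block[block]
    pos = np.empty(m, dtype=int)
    for c in np.unique(chrom):
        sel = chrom == c
        pos[sel] = 100_000 + 5_000 * np.arange(sel.sum())
    a_idx = rng.integers(0, 4, size=m)
    b_idx = (a_idx + rng.integers(1, 4, size=m)) % 4
    return pd.DataFrame({
        "snp_id": [f"rs{c}_{p}" for c, p in zip(chrom, pos)],
        "chrom": chrom, "pos": pos,
        "a1": _BASES[a_idx], "a2": _BASES[b_idx],
        "block": block,
    })


def _draw_haplotypes(n: int, thresholds: np.ndarray, block: np.ndarray,
                     rho: float, rng: np.random.Generator) -> np.ndarray:
    """n haplotypes as 0/1 allele indicators via the latent AR(1) Gaussian."""
    m = thresholds.size
    n_blocks = int(block[-1]) + 1
    bs = int(np.bincount(block).max())
    # AR dimension outermost so every update touches contiguous memory
    z = rng.standard_normal((bs, n * n_blocks), dtype=np.float32)
    if rho > 0.0 and bs > 1:
        rho32 = np.float32(rho)
        scale = np.float32(np.sqrt(1.0 - rho * rho))
        for k in range(1, bs):
            z[k] *= scale
            z[k] += rho32 * z[k - 1]
    latent = np.ascontiguousarray(
        z.reshape(bs, n, n_blocks).transpose(1, 2, 0)).reshape(n, n_blocks * bs)
    # keep the leading positions of each block (the last block may be partial)
    idx = block * bs + (np.arange(m) - np.searchsorted(block, block))
    thr32 = thresholds.astype(np.float32)
    return latent[:, idx] < thr32[None, :]


def _genetic_moments(effects, risk_freq):
    mean = float(np.sum(effects * 2.0 * risk_freq))
    var = float(np.sum(effects**2 * 2.0 * risk_freq * (1.0 - risk_freq)))
    return mean, var


def simulate_cohorts(config: SimConfig) -> tuple[list[Cohort], SimTruth]:
    """Draw ``n_cohorts`` independent cohorts sharing one SNP panel and one
    causal architecture; fully reproducible from ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    layout_rng = np.random.default_rng(root.spawn(1)[0])
    layout = _snp_layout(config, layout_rng)
    m = config.m_snps

    maf = layout_rng.uniform(config.maf_low, config.maf_high, size=m)
    n_causal = int(round(config.causal_fraction * m))
    causal_idx = layout_rng.choice(m, size=n_causal, replace=False)
    causal = np.zeros(m, dtype=bool)
    causal[causal_idx] = True
    effects = np.zeros(m)
    effects[causal] = np.abs(layout_rng.normal(0.0, config.effect_sd, n_causal))
    risk_is_minor = np.zeros(m, dtype=bool)
    risk_is_minor[causal] = (layout_rng.random(n_causal)
                             < config.minor_risk_prob)
    # a1 is the allele whose frequency is `maf` (the nominal minor allele)
    risk_allele = np.where(causal,
                           np.where(risk_is_minor, layout["a1"], layout["a2"]),
                           "")
    risk_freq = np.where(risk_is_minor, maf, 1.0 - maf)[causal]
    g_mean, g_var = _genetic_moments(effects[causal], risk_freq)
    threshold = g_mean + stats.norm.ppf(1.0 - config.prevalence) * np.sqrt(g_var + 1.0)

    block = layout["block"].to_numpy()
    snps = layout.drop(columns="block")

    bridge = _ArBridge(block, causal, config.ld_rho)
    cohorts: list[Cohort] = []
    liabilities: dict[str, np.ndarray] = {}
    cohort_seeds = root.spawn(1 + config.n_cohorts)[1:]
    for c in range(config.n_cohorts):
        rng = np.random.default_rng(cohort_seeds[c])
        target_maf = maf
        if config.maf_drift_sd > 0.0:
            target_maf = np.clip(maf + rng.normal(0.0, config.maf_drift_sd, m),
                                 1e-4, 0.5)
        thresholds = stats.norm.ppf(target_maf)
        name = f"cohort{c + 1}"
        cohort = _sample_one_cohort(config, thresholds, block, causal, effects,
                                    risk_is_minor, threshold, rng, name, snps,
                                    bridge)
        cohorts.append(cohort)
        liabilities[name] = cohort.extra.pop("liability")

    truth = SimTruth(
        snps=pd.DataFrame({"snp_id": snps["snp_id"], "maf_target": maf,
                           "causal": causal, "effect": effects,
                           "risk_allele": risk_allele}),
        liabilities=liabilities, threshold=threshold)
    return cohorts, truth


class _ArBridge:
    """Exact two-stage sampler for the blockwise AR(1) latent field.

    Stage 1 draws the latent only at causal positions (the AR process
    restricted to a subset of a Markov chain is itself Markov, with lag-
    dependent coefficients).  Stage 2 fills every remaining position of the
    accepted subjects conditionally: forward AR after the last known value,
    and the AR(1) Gaussian bridge between consecutive known values
    (``z_j | z_{j-1}=x, z_b=y`` is normal with mean
    ``[u(1-u^{2d})x + u^d(1-u^2)y] / (1-u^{2(d+1)})`` and variance
    ``(1-u^2)(1-u^{2d})/(1-u^{2(d+1)})`` for ``u = rho``, ``d = b - j``).
    The joint law of the full latent field equals the direct sampler's.
    """

    def __init__(self, block: np.ndarray, causal: np.ndarray, rho: float):
        self.rho = float(rho)
        self.block = block
        m = block.size
        self.n_blocks = int(block[-1]) + 1
        self.bs = int(np.bincount(block).max())
        first = np.searchsorted(block, block)
        self.offset = np.arange(m) - first           # position within block
        self.pad_idx = block * self.bs + self.offset  # position in padded grid
        self.causal_idx = np.flatnonzero(causal)
        u = self.rho

        # stage 1: previous causal SNP in the same block, and the lag
        ci = self.causal_idx
        prev_same = np.zeros(ci.size, dtype=bool)
        lag = np.zeros(ci.size, dtype=int)
        if ci.size:
            prev_same[1:] = block[ci[1:]] == block[ci[:-1]]
            lag[1:] = ci[1:] - ci[:-1]
        self.s1_coef = np.where(prev_same, u ** lag, 0.0)
        self.s1_sd = np.sqrt(1.0 - self.s1_coef**2)

        # stage 2: per padded position, the conditioning pattern
        nb, bs = self.n_blocks, self.bs
        known = np.zeros((nb, bs), dtype=bool)
        known[block[ci], self.offset[ci]] = True
        next_known = np.full((nb, bs), -1, dtype=int)
        for b in range(nb):
            nk = -1
            for k in range(bs - 1, -1, -1):
                next_known[b, k] = nk
                if known[b, k]:
                    nk = k
        d = np.where(next_known >= 0,
                     next_known - np.arange(bs)[None, :], 0)
        has_next = next_known >= 0
        kk = np.arange(bs)[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            det = 1.0 - u ** (2.0 * (d + 1))
            c_prev = np.where(has_next, u * (1.0 - u ** (2.0 * d)) / det, u)
            c_next = np.where(has_next, u**d * (1.0 - u**2) / det, 0.0)
            var = np.where(has_next,
                           (1.0 - u**2) * (1.0 - u ** (2.0 * d)) / det,
                           1.0 - u**2)
        # first position of a block has no left neighbour
        c_prev = np.where(kk == 0, 0.0, c_prev)
        c_next0 = np.where(has_next, u**d, 0.0)
        c_next = np.where(kk == 0, c_next0, c_next)
        var = np.where(kk == 0, 1.0 - c_next0**2, var)
        # known positions are copied, not sampled
        c_prev[known] = 0.0
        c_next[known] = 0.0
        var[known] = 0.0
        self.known = known
        self.next_known = np.maximum(next_known, 0)
        self.c_prev = c_prev
        self.c_next = c_next
        self.sd = np.sqrt(np.maximum(var, 0.0))

    def draw_causal(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """(n, n_causal) latent values at the causal positions."""
        nc = self.causal_idx.size
        z = rng.standard_normal((n, nc))
        for i in range(1, nc):
            if self.s1_coef[i] > 0.0:
                z[:, i] = self.s1_coef[i] * z[:, i - 1] + self.s1_sd[i] * z[:, i]
        return z

    def fill(self, z_causal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """(n, m) full latent field conditional on the causal values."""
        n = z_causal.shape[0]
        nb, bs = self.n_blocks, self.bs
        z = np.zeros((n, nb, bs))
        e = rng.standard_normal((n, nb, bs))
        ci = self.causal_idx
        z[:, self.block[ci], self.offset[ci]] = z_causal
        arange_nb = np.arange(nb)
        for k in range(bs):
            znext = z[:, arange_nb, self.next_known[:, k]]
            zprev = z[:, :, k - 1] if k > 0 else 0.0
            cand = (self.c_prev[None, :, k] * zprev
                    + self.c_next[None, :, k] * znext
                    + self.sd[None, :, k] * e[:, :, k])
            z[:, :, k] = np.where(self.known[None, :, k], z[:, :, k], cand)
        return z.reshape(n, nb * bs)[:, self.pad_idx]


def _sample_one_cohort(config: SimConfig, thresholds, block, causal, effects,
                       risk_is_minor, liab_threshold, rng,
                       name: str, snps: pd.DataFrame,
                       bridge: _ArBridge) -> Cohort:
    need_cases, need_controls = config.n_cases, config.n_controls
    # genotype dosage counts a1 (the nominal minor allele); risk dosage flips
    # where the risk allele is the major one
    eff_causal = effects[causal]
    flip = ~risk_is_minor[causal]
    thr_causal = thresholds[causal]

    kept_zc, kept_status, kept_liab = [], [], []
    n_cases_got = n_controls_got = 0
    batch = int(np.clip(np.ceil(need_cases / config.prevalence * 0.25),
                        256, 16384))
    # ~5x the expected number of candidate draws, with an absolute cap so an
    # unattainable request fails in bounded time
    expected = need_cases / config.prevalence + need_controls / (1 - config.prevalence)
    max_draws = int(min(5e6, 5 * expected + 20 * 16384))
    drawn = 0
    while n_cases_got < need_cases or n_controls_got < need_controls:
        if drawn >= max_draws:
            raise MaburdenError(
                "could not reach the requested case/control counts; "
                "prevalence too extreme for the requested n")
        zc1 = bridge.draw_causal(batch, rng)
        zc2 = bridge.draw_causal(batch, rng)
        geno_c = ((zc1 < thr_causal[None, :]).astype(np.int8)
                  + (zc2 < thr_causal[None, :]).astype(np.int8))
        drawn += batch
        gc = geno_c.astype(np.float64)
        risk_dos = np.where(flip[None, :], 2.0 - gc, gc)
        liab = risk_dos @ eff_causal + rng.standard_normal(batch)
        is_case = liab > liab_threshold
        take = np.zeros(batch, dtype=bool)
        if n_cases_got < need_cases:
            case_idx = np.flatnonzero(is_case)[:need_cases - n_cases_got]
            take[case_idx] = True
            n_cases_got += case_idx.size
        if n_controls_got < need_controls:
            ctrl_idx = np.flatnonzero(~is_case)[:need_controls - n_controls_got]
            take[ctrl_idx] = True
            n_controls_got += ctrl_idx.size
        if take.any():
            kept_zc.append(np.stack([zc1[take], zc2[take]], axis=0))
            kept_status.append(is_case[take].astype(np.int8))
            kept_liab.append(liab[take])

    zc = np.concatenate(kept_zc, axis=1)          # (2, n_kept, n_causal)
    status_all = np.concatenate(kept_status)
    liab_kept = np.concatenate(kept_liab)
    # fill the full panel for the accepted subjects only
    h1 = bridge.fill(zc[0], rng) < thresholds[None, :]
    h2 = bridge.fill(zc[1], rng) < thresholds[None, :]
    geno = h1.astype(np.int8) + h2.astype(np.int8)

    case_rows = np.flatnonzero(status_all == 1)
    ctrl_rows = np.flatnonzero(status_all == 0)
    order = np.concatenate([case_rows, ctrl_rows])
    dosage = geno[order].astype(float)
    status = np.concatenate([np.ones(need_cases, np.int8),
                             np.zeros(need_controls, np.int8)])
    liab_all = liab_kept[order]
    if config.missing_rate > 0.0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = np.nan

    subject_ids = np.array([f"{name}_S{i:05d}" for i in range(dosage.shape[0])],
                           dtype=object)
    genotypes = GenotypeMatrix(subject_ids, snps["snp_id"].to_numpy(object),
                               dosage)
    phen = Phenotype(subject_ids, status)
    cohort = Cohort(genotypes, snps.copy(), phen, name=name)
    cohort.extra["liability"] = liab_all
    return cohort


def empirical_ld_check(cohort: Cohort, config: SimConfig) -> pd.DataFrame:
    """Diagnostic: mean adjacent-pair r2 within blocks vs across block
    boundaries (the latter should be near zero by construction)."""
    m = cohort.n_snps
    bs = config.ld_block_size
    block = np.repeat(np.arange((m + bs - 1) // bs), bs)[:m]
    d = cohort.genotypes.dosage
    within, across = [], []
    for j in range(m - 1):
        same_chrom = (cohort.snps["chrom"].iat[j] == cohort.snps["chrom"].iat[j + 1])
        r2 = pairwise_r2(d[:, j], d[:, j + 1])
        if block[j] == block[j + 1] and same_chrom:
            within.append(r2)
        else:
            across.append(r2)
    return pd.DataFrame({
        "pair_class": ["within_block_adjacent", "cross_block_adjacent"],
        "mean_r2": [float(np.mean(within)) if within else np.nan,
                    float(np.mean(across)) if across else np.nan],
        "n_pairs": [len(within), len(across)],
    })
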