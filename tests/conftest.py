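import numpy as np
import pandas as pd
import pytest

import maburden as mb


@pytest.fixture
def tiny_cohort() -> mb.Cohort:
    """3 subjects x 2 SNPs with one missing genotype."""
    snps = pd.DataFrame({
        "snp_id": ["rs1", "rs2"], "chrom": [1, 2], "pos": [1000, 2000],
        "a1": ["A", "C"], "a2": ["G", "T"],
    })
    dosage = np.array([[0.0, 2.0], [1.0, np.nan], [2.0, 1.0]])
    subjects = np.array(["s1", "s2", "s3"], object)
    geno = mb.GenotypeMatrix(subjects, snps["snp_id"].to_numpy(object), dosage)
    phen = mb.Phenotype(subjects, np.array([0, 1, 1]), sex=np.array([1, 2, 1]))
    return mb.Cohort(geno, snps, phen, name="tiny")


def _sim(**kwargs):
    defaults = dict(n_cases=80, n_controls=80, m_snps=300, ld_block_size=20,
                    prevalence=0.2, missing_rate=0.02, seed=11,
                    minor_risk_prob=1.0)
    defaults.update(kwargs)
    return mb.simulate_cohorts(mb.SimConfig(**defaults))


@pytest.fixture(scope="session")
def sim_pair():
    """Two small cohorts with a planted minor-allele risk signal."""
    return _sim()


@pytest.fixture(scope="session")
def sim_cohort(sim_pair) -> mb.Cohort:
    return sim_pair[0][0]


@pytest.fixture(scope="session")
def sim_qc(sim_cohort):
    return mb.apply_qc(sim_cohort)[0]
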