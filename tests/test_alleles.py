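import numpy as np
import pandas as pd
import pytest
from scipy import stats

import maburden as mb
from maburden.alleles import (assign_minor_alleles, chi2_two_proportions,
                              compute_mac, f_test_variance, two_sample_z)


def _cohort(dosage, status, chrom=None):
    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    snps = pd.DataFrame({"snp_id": [f"r{j}" for j in range(m)],
                         "chrom": chrom if chrom is not None else 1,
                         "pos": np.arange(m) * 1000 + 1,
                         "a1": "A", "a2": "G"})
    subjects = np.array([f"s{i}" for i in range(n)], object)
    geno = mb.GenotypeMatrix(subjects, snps["snp_id"].to_numpy(object), dosage)
    return mb.Cohort(geno, snps, mb.Phenotype(subjects, np.asarray(status)))


class TestAssignMinorAlleles:
    def test_direct_frequency(self):
        """a1 dosages [0,0,1] over 3 controls -> a1 is minor with MAF 1/6."""
        cohort = _cohort([[0], [0], [1], [2]], [0, 0, 0, 1])
        a = assign_minor_alleles(cohort)
        assert a.minor_allele[0] == "A"
        assert a.maf[0] == pytest.approx(1 / 6)
        assert a.informative[0]

    def test_major_counted_allele_flips_orientation(self):
        cohort = _cohort([[2], [2], [1], [0]], [0, 0, 0, 1])
        a = assign_minor_alleles(cohort)
        assert a.minor_allele[0] == "G"
        assert not a.minor_is_a1[0]
        assert a.maf[0] == pytest.approx(1 / 6)

    def test_tie_at_half_is_non_informative(self):
        cohort = _cohort([[1], [1], [1]], [0, 0, 1])
        a = assign_minor_alleles(cohort)
        assert not a.informative[0]

    def test_monomorphic_is_non_informative(self):
        cohort = _cohort([[0], [0], [2]], [0, 0, 1])
        a = assign_minor_alleles(cohort)
        assert not a.informative[0]
        assert a.maf[0] == 0.0

    def test_all_missing_in_controls_flagged(self):
        cohort = _cohort([[np.nan], [np.nan], [1]], [0, 0, 1])
        a = assign_minor_alleles(cohort)
        assert not a.informative[0]
        assert np.isnan(a.maf[0])

    def test_matches_brute_force_counting(self):
        """20-SNP random fixture vs direct per-SNP allele counting."""
        rng = np.random.default_rng(2)
        dosage = rng.integers(0, 3, size=(30, 20)).astype(float)
        dosage[rng.random(dosage.shape) < 0.1] = np.nan
        status = np.r_[np.zeros(18, int), np.ones(12, int)]
        cohort = _cohort(dosage, status)
        a = assign_minor_alleles(cohort)
        for j in range(20):
            col = dosage[status == 0, j]
            col = col[~np.isnan(col)]
            f_a1 = col.sum() / (2 * len(col))
            if f_a1 in (0.0, 0.5, 1.0):
                assert not a.informative[j]
            else:
                expect = "A" if f_a1 < 0.5 else "G"
                assert a.minor_allele[j] == expect
                assert a.maf[j] == pytest.approx(min(f_a1, 1 - f_a1))


class TestComputeMac:
    def _assign(self, cohort):
        return assign_minor_alleles(cohort)

    def test_normalization_anchors(self):
        """All-major -> 0; all-het -> 0.5; all-minor-homozygous -> 1."""
        cohort = _cohort([[0, 0], [1, 1], [2, 2], [0, 1], [0, 0]],
                         [0, 0, 0, 1, 0])
        a = self._assign(cohort)
        mac = compute_mac(cohort.genotypes, a)
        assert mac.mac[0] == 0.0
        assert mac.mac[1] == 0.5
        assert mac.mac[2] == 1.0

    def test_hand_sums_with_missing(self):
        """Dosages [0,1,2] -> 3/6; [0,NaN,1] -> 1/4."""
        cohort = _cohort([[0, 1, 2], [0, np.nan, 1],
                          [0, 0, 0], [1, 1, 0], [0, 1, 0]], [0, 0, 0, 0, 1])
        a = self._assign(cohort)
        mac = compute_mac(cohort.genotypes, a)
        assert mac.mac[0] == pytest.approx(0.5)
        assert mac.n_used[0] == 3
        assert mac.mac[1] == pytest.approx(0.25)
        assert mac.n_used[1] == 2

    def test_per_snp_denominator_option(self):
        cohort = _cohort([[0, 1, 2], [1, 1, 1], [0, 0, 1], [1, 0, 0]], [0, 0, 0, 1])
        a = self._assign(cohort)
        per_allele = compute_mac(cohort.genotypes, a, "per_allele")
        per_snp = compute_mac(cohort.genotypes, a, "per_snp")
        np.testing.assert_allclose(per_snp.mac, 2 * per_allele.mac)

    def test_subject_with_no_usable_snps_flagged(self):
        cohort = _cohort([[np.nan, np.nan], [1, 0], [0, 1], [2, 0]], [0, 0, 0, 1])
        a = self._assign(cohort)
        mac = compute_mac(cohort.genotypes, a)
        assert np.isnan(mac.mac[0])
        assert mac.n_used[0] == 0

    def test_invariant_under_snp_reordering(self, sim_qc):
        a = assign_minor_alleles(sim_qc)
        mac = compute_mac(sim_qc.genotypes, a)
        rng = np.random.default_rng(0)
        perm = rng.permutation(sim_qc.n_snps)
        shuffled = sim_qc.take_snps(perm)
        mac2 = compute_mac(shuffled.genotypes, assign_minor_alleles(shuffled))
        np.testing.assert_allclose(mac.mac, mac2.mac, atol=1e-12)

    def test_invariant_under_counted_allele_relabel(self):
        """Flipping which allele the matrix counts leaves MAC unchanged."""
        rng = np.random.default_rng(3)
        dosage = rng.integers(0, 3, (40, 10)).astype(float)
        status = np.r_[np.zeros(25, int), np.ones(15, int)]
        cohort = _cohort(dosage, status)
        mac1 = compute_mac(cohort.genotypes,
                           assign_minor_alleles(cohort)).mac
        flipped = cohort.snps.copy()
        flipped[["a1", "a2"]] = flipped[["a2", "a1"]].to_numpy()
        geno2 = mb.GenotypeMatrix(cohort.genotypes.subject_ids,
                                  cohort.genotypes.snp_ids,
                                  2.0 - cohort.genotypes.dosage)
        cohort2 = mb.Cohort(geno2, flipped, cohort.phenotype)
        mac2 = compute_mac(cohort2.genotypes,
                           assign_minor_alleles(cohort2)).mac
        np.testing.assert_allclose(mac1, mac2, atol=1e-12)

    def test_expected_mac_is_mean_panel_maf(self):
        """Under HWE the expected MAC equals the mean control MAF."""
        rng = np.random.default_rng(4)
        maf = rng.uniform(0.05, 0.45, 200)
        dosage = rng.binomial(2, maf[None, :], (2000, 200)).astype(float)
        status = np.r_[np.zeros(1500, int), np.ones(500, int)]
        cohort = _cohort(dosage, status)
        a = assign_minor_alleles(cohort)
        mac = compute_mac(cohort.genotypes, a)
        assert np.nanmean(mac.mac) == pytest.approx(np.mean(a.maf[a.informative]),
                                                    abs=0.005)


class TestTwoSampleZ:
    def test_identical_groups_null(self):
        z, p, _, _ = two_sample_z([1, 2, 3], [1, 2, 3])
        assert z == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        """a={1,2,3}, b={4,5,6}: z = -3/sqrt(2/3) = -3.674."""
        z, p, means, sems = two_sample_z([1, 2, 3], [4, 5, 6])
        assert z == pytest.approx(-3.6742346, abs=1e-6)
        assert p == pytest.approx(2.39e-4, rel=0.01)
        assert means == (2.0, 5.0)
        assert sems[0] == pytest.approx(np.sqrt(1 / 3))

    def test_antisymmetric(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=20), rng.normal(1, 1, size=25)
        z1, p1, _, _ = two_sample_z(a, b)
        z2, p2, _, _ = two_sample_z(b, a)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_zero_variance(self):
        z, p, _, _ = two_sample_z([1, 1, 1], [1, 1])
        assert (z, p) == (0.0, 1.0)
        z, p, _, _ = two_sample_z([2, 2], [1, 1, 1])
        assert np.isinf(z) and p == 0.0

    def test_null_calibration(self):
        """Rejection rate at alpha=0.05 sits inside its binomial band."""
        rng = np.random.default_rng(7)
        n_rep, n = 4000, 50
        a = rng.normal(size=(n_rep, n))
        b = rng.normal(size=(n_rep, n))
        va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        z = (a.mean(1) - b.mean(1)) / np.sqrt(va / n + vb / n)
        pvals = 2 * stats.norm.sf(np.abs(z))
        # spot-check the vectorised oracle against the implementation
        zz, pp, _, _ = two_sample_z(a[0], b[0])
        assert zz == pytest.approx(z[0]) and pp == pytest.approx(pvals[0])
        rate = (pvals < 0.05).mean()
        band = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < band + 0.005


class TestFTest:
    def test_equal_variances(self):
        f, p = f_test_variance([1, 2, 3], [4, 5, 6])
        assert f == 1.0 and p == 1.0

    def test_hand_computed_f22(self):
        """s2=1 vs s2=4 on (2,2) df: F=4, two-tailed p = 2*(1-4/5) = 0.4."""
        f, p = f_test_variance([1, 2, 3], [2, 4, 6])
        assert f == pytest.approx(4.0)
        assert p == pytest.approx(0.4, abs=1e-10)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=10), rng.normal(0, 2, size=15)
        assert f_test_variance(a, b) == pytest.approx(f_test_variance(b, a))

    def test_zero_variance_denominator(self):
        f, p = f_test_variance([1, 2, 3], [5, 5, 5])
        assert np.isinf(f) and p == 0.0


class TestChi2TwoProportions:
    def test_equal_proportions(self):
        chi2, p = chi2_two_proportions(10, 100, 10, 100)
        assert chi2 == 0.0 and p == 1.0

    def test_hand_computed_2x2(self):
        chi2, p = chi2_two_proportions(20, 100, 10, 100)
        assert chi2 == pytest.approx(3.9216, abs=1e-3)
        assert p == pytest.approx(0.0477, abs=5e-4)

    def test_degenerate_pooled(self):
        assert chi2_two_proportions(0, 10, 0, 20) == (0.0, 1.0)
        assert chi2_two_proportions(10, 10, 20, 20) == (0.0, 1.0)

    def test_matches_scipy_oracle(self):
        """Agreement with the generic 2x2 chi-square over random tables."""
        rng = np.random.default_rng(9)
        for _ in range(300):
            n1, n2 = rng.integers(5, 200, 2)
            x1, x2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            pooled = (x1 + x2) / (n1 + n2)
            if pooled in (0.0, 1.0):
                continue
            table = [[x1, n1 - x1], [x2, n2 - x2]]
            if min(min(r) for r in table) == 0 and (x1 + x2) in (0, n1 + n2):
                continue
            ref = stats.chi2_contingency(table, correction=False)
            chi2, p = chi2_two_proportions(int(x1), int(n1), int(x2), int(n2))
            assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(mb.MaburdenError):
            chi2_two_proportions(5, 4, 1, 10)
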