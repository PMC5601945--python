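import numpy as np
import pandas as pd
import pytest

import maburden as mb
from maburden.grid import (DEFAULT_SCREEN, MAF_CUTOFFS, P_GRID, R2_THRESHOLDS,
                           GridResult, ModelSpec, TrainingFit, build_grid,
                           external_cv, harmonize_cohorts, internal_cv_10fold,
                           make_folds, select_best_model)


@pytest.fixture(scope="module")
def training_fit(sim_qc):
    return TrainingFit(sim_qc)


class TestBuildGrid:
    def test_p_grid_has_26_values(self):
        assert len(P_GRID) == 26
        assert len(MAF_CUTOFFS) == 5
        assert len(R2_THRESHOLDS) == 8

    def test_grid_sizes_130_208_234(self, training_fit):
        assert len(build_grid(training_fit, "wgrs", "total_by_maf")) == 130
        assert len(build_grid(training_fit, "wgrs", "ld_independent")) == 208
        assert len(build_grid(training_fit, "prs")) == 234

    def test_p_thresholds_nest(self, training_fit):
        """Within a filter, stricter p gives a subset of the looser list."""
        specs = build_grid(training_fit, "wgrs", "total_by_maf")
        by_cell = {(s.maf_cutoff, s.p_threshold): set(s.snp_ids) for s in specs}
        for maf in MAF_CUTOFFS:
            for tight, loose in zip(P_GRID[1:], P_GRID[:-1]):
                assert by_cell[(maf, tight)] <= by_cell[(maf, loose)]

    def test_cell_lists_match_brute_force_filter(self, sim_qc, training_fit):
        """Each cell equals an independent re-evaluation of its filters."""
        a = training_fit.assignment
        wtab = training_fit.weights.table.set_index("snp_id")
        specs = build_grid(training_fit, "wgrs", "total_by_maf")
        rng = np.random.default_rng(0)
        for spec in rng.choice(specs, size=12, replace=False):
            expect = []
            for j, snp in enumerate(sim_qc.genotypes.snp_ids):
                if not a.informative[j] or snp not in wtab.index:
                    continue
                row = wtab.loc[snp]
                if (row["usable"] and row["p"] < spec.p_threshold
                        and a.maf[j] < spec.maf_cutoff):
                    expect.append(snp)
            assert list(spec.snp_ids) == expect

    def test_ld_cells_subset_of_pruned_set(self, training_fit):
        specs = build_grid(training_fit, "wgrs", "ld_independent")
        for spec in specs[:30]:
            assert set(spec.snp_ids) <= training_fit.pruned(spec.r2_threshold)

    def test_spec_validation(self):
        with pytest.raises(mb.MaburdenError):
            ModelSpec("wgrs", "total_by_maf", 0.5)  # neither filter set
        with pytest.raises(mb.MaburdenError):
            ModelSpec("wgrs", "total_by_maf", 0.5, maf_cutoff=0.3,
                      r2_threshold=0.5)


class TestHarmonization:
    def test_swapped_alleles_reconciled(self, sim_qc):
        flipped = sim_qc.snps.copy()
        flipped[["a1", "a2"]] = flipped[["a2", "a1"]].to_numpy()
        geno = mb.GenotypeMatrix(
            np.array([f"x{i}" for i in range(sim_qc.n_subjects)], object),
            sim_qc.genotypes.snp_ids, 2.0 - sim_qc.genotypes.dosage)
        phen = mb.Phenotype(geno.subject_ids, sim_qc.phenotype.status)
        other = mb.Cohort(geno, flipped, phen, name="flipped")
        t2, v2, dropped = harmonize_cohorts(sim_qc, other)
        assert dropped == []
        np.testing.assert_array_equal(t2.genotypes.dosage, v2.genotypes.dosage)
        assert list(v2.snps["a1"]) == list(t2.snps["a1"])

    def test_irreconcilable_and_ambiguous_dropped(self, tiny_cohort):
        other = tiny_cohort.snps.copy()
        other.loc[0, ["a1", "a2"]] = ["A", "T"]  # training says A/G: mismatch
        geno = mb.GenotypeMatrix(
            np.array(["y1", "y2", "y3"], object),
            tiny_cohort.genotypes.snp_ids, tiny_cohort.genotypes.dosage)
        phen = mb.Phenotype(geno.subject_ids, tiny_cohort.phenotype.status)
        v = mb.Cohort(geno, other, phen)
        _, v2, dropped = harmonize_cohorts(tiny_cohort, v)
        assert dropped == ["rs1"]
        assert list(v2.genotypes.snp_ids) == ["rs2"]

    def test_strand_flip_applied_when_unambiguous(self, tiny_cohort):
        other = tiny_cohort.snps.copy()
        # rs1 is A/G; the complement T/C is an unambiguous strand flip
        other.loc[0, ["a1", "a2"]] = ["T", "C"]
        geno = mb.GenotypeMatrix(
            np.array(["y1", "y2", "y3"], object),
            tiny_cohort.genotypes.snp_ids, tiny_cohort.genotypes.dosage)
        phen = mb.Phenotype(geno.subject_ids, tiny_cohort.phenotype.status)
        _, v2, dropped = harmonize_cohorts(tiny_cohort, mb.Cohort(geno, other, phen))
        assert dropped == []
        np.testing.assert_array_equal(v2.genotypes.dosage[:, 0],
                                      tiny_cohort.genotypes.dosage[:, 0])


class TestExternalCv:
    def test_subject_overlap_is_hard_error(self, sim_qc):
        with pytest.raises(mb.MaburdenError, match="overlap"):
            external_cv(sim_qc, sim_qc)

    def test_planted_signal_detected(self, sim_pair):
        """With a strong minor-allele-oriented signal the validation AUC of
        permissive cells exceeds 0.5."""
        (train, valid), _ = sim_pair
        result = external_cv(train, valid, "wgrs", "total_by_maf",
                             compute_delta_r2=False)
        assert len(result.frame) == 130
        permissive = result.frame[(result.frame["p_threshold"] == 1.0)
                                  & (result.frame["maf_cutoff"] == 0.5)]
        assert permissive["auc"].iloc[0] > 0.55

    def test_provenance_recorded(self, sim_pair):
        (train, valid), _ = sim_pair
        result = external_cv(train, valid, "wgrs", "total_by_maf",
                             compute_delta_r2=False)
        assert result.provenance["training"] == train.name
        assert result.provenance["validation"] == valid.name


class TestInternalCv:
    def test_fold_sizes_2154(self):
        """n = 2154 splits into four folds of 216 and six of 215."""
        folds = make_folds(2154, 10, np.random.default_rng(0))
        sizes = sorted((len(f) for f in folds), reverse=True)
        assert sizes == [216] * 4 + [215] * 6
        assert len(np.unique(np.concatenate(folds))) == 2154

    def test_deterministic_under_seed(self, sim_qc):
        spec = ModelSpec("wgrs", "total_by_maf", 0.3, maf_cutoff=0.5)
        r1 = internal_cv_10fold(sim_qc, spec, seed=42)
        r2 = internal_cv_10fold(sim_qc, spec, seed=42)
        assert r1[0] == r2[0] and r1[1] == r2[1]
        pd.testing.assert_frame_equal(r1[2], r2[2])

    def test_signal_cohort_beats_chance(self, sim_qc):
        spec = ModelSpec("wgrs", "total_by_maf", 1.0, maf_cutoff=0.5)
        mean_auc, _, per_fold = internal_cv_10fold(sim_qc, spec, seed=3)
        assert len(per_fold) == 10
        assert mean_auc > 0.5

    def test_cohort_smaller_than_folds_rejected(self, tiny_cohort):
        spec = ModelSpec("wgrs", "total_by_maf", 1.0, maf_cutoff=0.5)
        with pytest.raises(mb.MaburdenError):
            internal_cv_10fold(tiny_cohort, spec, seed=0)


def _grid_result(rows):
    frame = pd.DataFrame(rows)
    frame["evaluable"] = frame["n_snps"] > 0
    for col in ("auc_lo", "auc_hi", "tpr_lo", "tpr_hi"):
        frame[col] = np.nan
    frame["n_cases"] = frame["n_controls"] = 50
    specs = [ModelSpec(r["score_type"], r["filter_kind"], r["p_threshold"],
                       maf_cutoff=r.get("maf_cutoff"),
                       r2_threshold=r.get("r2_threshold"),
                       snp_ids=("s",) * r["n_snps"], n_snps=r["n_snps"])
             for r in rows]
    return GridResult(frame, specs)


class TestSelectBestModel:
    def _row(self, p, auc, tpr, dr2, n, maf=0.5):
        return {"score_type": "wgrs", "filter_kind": "total_by_maf",
                "maf_cutoff": maf, "r2_threshold": None, "p_threshold": p,
                "n_snps": n, "auc": auc, "tpr": tpr, "delta_r2": dr2}

    def test_dominating_model_selected(self):
        gr = _grid_result([self._row(0.5, 0.60, 0.05, 0.04, 100),
                           self._row(0.4, 0.62, 0.06, 0.05, 120)])
        best = select_best_model(gr, screen=None)
        assert best.p_threshold == 0.4

    def test_numerical_tie_broken_by_fewer_snps(self):
        gr = _grid_result([
            self._row(0.5, 0.62, 0.06, 0.05, 120),
            self._row(0.4, 0.62 + 1e-12, 0.06 - 1e-12, 0.05, 80)])
        best = select_best_model(gr, screen=None)
        assert best.n_snps == 80

    def test_screen_excludes_weak_models(self):
        gr = _grid_result([self._row(0.5, 0.56, 0.05, 0.04, 100),
                           self._row(0.4, 0.60, 0.01, 0.05, 120)])
        assert select_best_model(gr, screen="default") is None
        assert gr.provenance["selection"] == "no model passed the screen"

    def test_default_screen_thresholds(self):
        assert DEFAULT_SCREEN["total_by_maf"] == (0.02, 0.57)
        assert DEFAULT_SCREEN["ld_independent"] == (0.0278, 0.57)

    def test_matches_exhaustive_scan_oracle(self):
        """Random grids: selection equals a brute-force scan of the same
        ranking rule."""
        rng = np.random.default_rng(1)
        for _ in range(30):
            rows = [self._row(p, float(rng.choice([0.55, 0.60, 0.65])),
                              float(rng.choice([0.01, 0.03, 0.05])),
                              float(rng.choice([0.02, 0.04])),
                              int(rng.integers(1, 500)))
                    for p in rng.choice(P_GRID, size=8, replace=False)]
            gr = _grid_result(rows)
            best = select_best_model(gr, screen=None)
            ranked = sorted(
                range(len(rows)),
                key=lambda i: (-round(rows[i]["auc"], 9),
                               -round(rows[i]["tpr"], 9),
                               -round(rows[i]["delta_r2"], 9),
                               rows[i]["n_snps"],
                               gr.specs[i].key))
            assert gr.selected == ranked[0]
            assert best is gr.specs[ranked[0]]

    def test_unevaluable_rows_ignored(self):
        gr = _grid_result([self._row(0.5, 0.99, 0.5, 0.5, 0),
                           self._row(0.4, 0.60, 0.03, 0.02, 50)])
        best = select_best_model(gr, screen=None)
        assert best.n_snps == 50
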