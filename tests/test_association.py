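"""Age/sex association: Wilcoxon + Spearman with BH, cluster assignment,
the overlap contingency test and sex-stratified concordance."""

import numpy as np
import pandas as pd
import pytest

import bloodmir as bm
from bloodmir.datatypes import records_to_frame


class TestAssociate:
    def test_planted_sex_effect_recovered(self, recovery_cohort, recovery_records):
        expr, meta, truth = recovery_cohort
        fr = records_to_frame(recovery_records)
        sex_only = truth.mirnas_of_class("sex_only")
        hit = (fr.loc[sex_only, "sex_p_adj"] < 0.05)
        assert hit.mean() >= 0.9
        assert fr.loc[sex_only, "sc"].abs().median() < 0.1

    def test_age_recovery_sensitivity_and_fdr(self, recovery_cohort,
                                              recovery_records):
        expr, meta, truth = recovery_cohort
        fr = records_to_frame(recovery_records)
        sig = fr["sc_p_adj"] < 0.05
        age_classes = {"age_up_linear", "age_down_linear"}
        is_age = pd.Series({f: truth.mirna_class[f] in age_classes
                            for f in fr.index})
        sens = (sig & is_age).sum() / is_age.sum()
        negatives = pd.Series({f: truth.mirna_class[f] in
                               {"null", "sex_only", "disease_only"}
                               for f in fr.index})
        fdr = (sig & negatives).sum() / max(int(sig.sum()), 1)
        assert sens >= 0.9
        assert fdr <= 0.1

    def test_constant_mirna_flagged_missing(self):
        expr, meta, _ = bm.simulate_cohort(n_samples=100, n_mirnas=5, seed=0)
        flat = expr.values.copy()
        flat.iloc[0] = 1.0
        records = bm.associate(bm.ExpressionMatrix(flat), meta)
        r0 = records[0]
        assert r0.sc is None and r0.sex_p is None


class TestAssignClusters:
    @pytest.mark.parametrize("sc,expected", [
        (-0.5, 1), (-0.2, 2), (-0.15, 2), (-0.1, 3), (0.0, 3),
        (0.1, 3), (0.15, 4), (0.2, 4), (0.25, 5),
    ])
    def test_threshold_table(self, sc, expected):
        assert bm.assign_cluster(sc) == expected

    def test_sizes_sum_and_idempotent(self, recovery_records):
        fr = records_to_frame(recovery_records)
        sizes = fr["cluster"].value_counts()
        assert sizes.sum() == len(fr)
        again = bm.assign_clusters(recovery_records)
        assert records_to_frame(again)["cluster"].equals(fr["cluster"])


class TestOverlapTest:
    def test_cohort_scale_counts(self):
        """At the published universe/overlap counts the association between
        the age- and sex-significant sets is not significant."""
        res = bm.overlap_test(2549, 1568, 362, 231)
        assert res.fisher_p == pytest.approx(0.35, abs=0.01)
        assert res.chi2_p == pytest.approx(0.36, abs=0.01)
        assert sum(sum(row) for row in res.table) == 2549

    def test_independence_exact_table(self):
        # margins 5, 4 in a universe of 10: observed 2 is the modal table
        res = bm.overlap_test(10, 5, 4, 2)
        assert res.fisher_p == pytest.approx(1.0)

    def test_maximal_association_minimal_p(self):
        res = bm.overlap_test(100, 20, 20, 20)
        base = bm.overlap_test(100, 20, 20, 10)
        assert res.fisher_p < base.fisher_p

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            bm.overlap_test(10, 5, 4, 5)
        with pytest.raises(ValueError):
            bm.overlap_test(10, 8, 8, 2)

    def test_fisher_close_to_yates_chi2_for_large_cells(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            neither = int(rng.integers(200, 800))
            both = int(rng.integers(60, 300))
            a_only = int(rng.integers(60, 300))
            b_only = int(rng.integers(60, 300))
            n = both + a_only + b_only + neither
            res = bm.overlap_test(n, both + a_only, both + b_only, both)
            expected_min = min(
                (both + a_only) * (both + b_only),
                (both + a_only) * (b_only + neither),
                (a_only + neither) * (both + b_only),
                (a_only + neither) * (b_only + neither)) / n
            if expected_min >= 50:
                assert abs(res.fisher_p - res.chi2_p) < 0.05


class TestSexConcordance:
    def test_relabelled_identical_samples_give_rho_one(self):
        expr, meta, _ = bm.simulate_cohort(n_samples=200, n_mirnas=50, seed=9)
        # duplicate every sample, label one copy male and the other female
        v = expr.values
        dup = pd.concat([v.add_suffix("_m", axis=1), v.add_suffix("_f", axis=1)],
                        axis=1)
        t = meta.table
        mt = pd.concat([
            t.assign(sex="male").set_axis(t.index + "_m"),
            t.assign(sex="female").set_axis(t.index + "_f")])
        rho, p, classes = bm.sex_stratified_concordance(
            bm.ExpressionMatrix(dup), bm.SampleMetadata(mt))
        assert rho == pytest.approx(1.0)

    def test_sex_independent_age_effects_concordant(self):
        expr, meta, _ = bm.simulate_cohort(n_samples=1000, n_mirnas=300, seed=10)
        rho, p, classes = bm.sex_stratified_concordance(expr, meta)
        assert rho > 0.8
        assert p < 1e-10
        assert set(classes.values()) <= {"both", "males_only",
                                         "females_only", "neither"}
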