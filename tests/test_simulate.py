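"""Synthetic cohort generator: determinism, planted-class calibration and
the arm/protein/presence sub-generators."""

import numpy as np
import pandas as pd
import pytest

import bloodmir as bm
from bloodmir.stats import spearman_vs_vector


class TestSimulateCohort:
    def test_deterministic_per_seed(self):
        a = bm.simulate_cohort(n_samples=60, n_mirnas=30, seed=42)
        b = bm.simulate_cohort(n_samples=60, n_mirnas=30, seed=42)
        assert np.array_equal(a[0].values, b[0].values)
        assert a[1].table.equals(b[1].table)
        assert a[2].mirna_class == b[2].mirna_class
        c = bm.simulate_cohort(n_samples=60, n_mirnas=30, seed=43)
        assert not np.array_equal(a[0].values, c[0].values)

    def test_null_model_type_I_rate(self):
        """With no planted classes, the BH-significant fraction stays small."""
        expr, meta, truth = bm.simulate_cohort(
            n_samples=300, n_mirnas=400, seed=3,
            fractions={c: 0.0 for c in bm.simulate.DEFAULT_FRACTIONS})
        assert set(truth.mirna_class.values()) == {"null"}
        _, p = spearman_vs_vector(expr.values.to_numpy(float),
                                  meta.ages.to_numpy(float))
        from bloodmir.stats import adjust_bh
        frac_sig = (adjust_bh(p) < 0.05).mean()
        assert frac_sig <= 0.05

    def test_planted_linear_sc_calibrated(self, recovery_cohort):
        """Mean realized |SC| of the linear age classes is ~0.3 (+-0.05)."""
        expr, meta, truth = recovery_cohort
        sc, _ = spearman_vs_vector(expr.values.to_numpy(float),
                                   meta.ages.to_numpy(float))
        sc = pd.Series(sc, index=expr.feature_ids)
        for cls, sign in (("age_up_linear", 1), ("age_down_linear", -1)):
            members = truth.mirnas_of_class(cls)
            assert len(members) == 200  # 20% of 1000
            mean_sc = sc[members].mean()
            assert sign * mean_sc == pytest.approx(0.3, abs=0.05)

    def test_truth_classes_partition(self, small_cohort):
        expr, _, truth = small_cohort
        assert sorted(truth.mirna_class) == sorted(expr.feature_ids)
        assert set(truth.mirna_class.values()) <= set(bm.simulate.MIRNA_CLASSES)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="fractions"):
            bm.simulate_cohort(n_samples=50, n_mirnas=10,
                               fractions={"null": 0.9, "age_up_linear": 0.3})
        with pytest.raises(ValueError, match="age range"):
            bm.simulate_cohort(n_samples=50, n_mirnas=10, age_range=(50, 50))
        with pytest.raises(ValueError, match="n_samples"):
            bm.simulate_cohort(n_samples=10, n_mirnas=10)


class TestSimulateArmPairs:
    @pytest.fixture(scope="class")
    @staticmethod
    def cohort_meta():
        _, meta, _ = bm.simulate_cohort(n_samples=400, n_mirnas=10, seed=21)
        return meta

    def test_no_switches_planted_none_detected(self, cohort_meta):
        arm, pairs, truth = bm.simulate_arm_pairs(30, 0, 0.3, cohort_meta, seed=1)
        assert all(not v["switch"] for v in truth.arm_switch.values())
        recs = bm.detect_arm_shifts(arm, pairs, cohort_meta)
        assert recs == []

    def test_planted_drift_realized(self, cohort_meta):
        """Drift 0.3 in the mean 5' fraction yields a per-age-mean range
        of at least 0.2."""
        arm, pairs, truth = bm.simulate_arm_pairs(20, 20, 0.3, cohort_meta, seed=2)
        ages = cohort_meta.ages.to_numpy()
        for _, row in pairs.iterrows():
            v5 = 2.0 ** arm.values.loc[row["mirna_5p"]].to_numpy()
            v3 = 2.0 ** arm.values.loc[row["mirna_3p"]].to_numpy()
            frac = v5 / (v5 + v3)
            means = pd.Series(frac).groupby(ages).mean()
            assert means.max() - means.min() >= 0.2

    def test_switched_pair_arms_anticorrelated(self, cohort_meta):
        arm, pairs, truth = bm.simulate_arm_pairs(10, 10, 0.35, cohort_meta, seed=3)
        ages = cohort_meta.ages.to_numpy(float)
        sc, _ = spearman_vs_vector(arm.values.to_numpy(float), ages)
        sc = pd.Series(sc, index=arm.feature_ids)
        for _, row in pairs.iterrows():
            assert np.sign(sc[row["mirna_5p"]]) == -np.sign(sc[row["mirna_3p"]])

    def test_bad_magnitude_rejected(self, cohort_meta):
        with pytest.raises(ValueError):
            bm.simulate_arm_pairs(5, 1, 1.5, cohort_meta, seed=0)
        with pytest.raises(ValueError):
            bm.simulate_arm_pairs(5, 6, 0.3, cohort_meta, seed=0)


class TestSimulateProteins:
    @pytest.fixture(scope="class")
    @staticmethod
    def wired():
        expr, meta, truth = bm.simulate_cohort(n_samples=400, n_mirnas=600, seed=7)
        prot, inter, ledger = bm.simulate_proteins_and_interactions(
            expr, meta, truth, n_proteins=200, seed=7)
        return expr, meta, truth, prot, inter, ledger

    def test_hub_proteins_wired_to_at_least_nine(self, wired):
        *_, inter, ledger = wired
        strong = inter.strong()
        hubs = {g for _, g in ledger.true_regulations}
        for hub in hubs:
            assert strong[strong["gene_id"] == hub]["mirna_id"].nunique() >= 9

    def test_true_regulations_reference_planted_down_mirnas(self, wired):
        _, _, truth, _, _, ledger = wired
        down = set(truth.mirnas_of_class("age_down_linear"))
        assert {m for m, _ in ledger.true_regulations} <= down

    def test_protein_values_positive_on_linear_scale(self, wired):
        prot = wired[3]
        assert (10.0 ** prot.values.to_numpy() > 0).all()

    def test_positive_coupling_rejected(self, wired):
        expr, meta, truth, *_ = wired
        with pytest.raises(ValueError, match="coupling"):
            bm.simulate_proteins_and_interactions(expr, meta, truth,
                                                  coupling=0.5, seed=0)


class TestCompoundPresence:
    def test_uniform_bias_rate_within_ci(self, small_cohort):
        expr, _, truth = small_cohort
        pres = bm.simulate_compound_presence(expr.feature_ids, truth,
                                             class_bias={}, base_rate=0.4,
                                             seed=5)
        rates = pres.mean(axis=0)
        n = pres.shape[0]
        ci = 3 * np.sqrt(0.4 * 0.6 / n)
        assert ((rates - 0.4).abs() <= ci).all()

    def test_planted_bias_raises_presence(self, small_cohort):
        expr, _, truth = small_cohort
        pres = bm.simulate_compound_presence(expr.feature_ids, truth, seed=5)
        up = truth.mirnas_of_class("age_up_linear")
        null = truth.mirnas_of_class("null")
        assert pres.loc[up, "CD19"].mean() > pres.loc[null, "CD19"].mean()

    def test_duplicate_compound_labels_rejected(self, small_cohort):
        expr, _, truth = small_cohort
        with pytest.raises(ValueError):
            bm.simulate_compound_presence(expr.feature_ids, truth,
                                          compounds=["a", "a"], seed=0)
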