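"""SOM biomarker maps: condition vectors, Kohonen training, cell heatmaps
and hierarchical clustering of biomarker sets."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

import bloodmir as bm
from bloodmir.simulate import child_seed


@pytest.fixture(scope="module")
def som_setup():
    expr, meta, truth = bm.simulate_cohort(n_samples=1000, n_mirnas=1000,
                                           seed=23)
    vectors = bm.biomarker_vectors(expr, meta)
    model = bm.train_som(vectors, bm.SomParams(seed=23))
    return expr, meta, truth, vectors, model


class TestBiomarkerVectors:
    def test_selects_exactly_801_top_expressed(self, som_setup):
        expr, meta, _, vectors, _ = som_setup
        assert vectors.shape[0] == 801
        medians = expr.values.median(axis=1)
        cutoff = medians.sort_values(ascending=False).iloc[800]
        assert medians[vectors.index].min() >= cutoff

    def test_twelve_conditions(self, som_setup):
        vectors = som_setup[3]
        assert vectors.shape[1] == 12
        assert {c.split("_")[1] for c in vectors.columns} == {"all", "young", "old"}

    def test_no_effect_mirnas_near_zero(self, som_setup):
        _, _, truth, vectors, _ = som_setup
        null = [m for m in truth.mirnas_of_class("null") if m in vectors.index]
        assert vectors.loc[null].abs().mean().mean() < 0.2


class TestTrainSom:
    def test_full_occupancy_mean_members(self, som_setup):
        model = som_setup[4]
        occ = model.occupancy()
        assert (occ > 0).all()
        assert occ.mean() == pytest.approx(801 / 100)

    def test_bit_reproducible_per_seed(self, som_setup):
        vectors = som_setup[3]
        m1 = bm.train_som(vectors, bm.SomParams(seed=5))
        m2 = bm.train_som(vectors, bm.SomParams(seed=5))
        assert np.array_equal(m1.codebooks, m2.codebooks)
        assert m1.assignment.equals(m2.assignment)

    def test_training_beats_shuffled_assignment(self, som_setup):
        """Trained quantization error is below a random-assignment
        baseline (intra-cell coherence)."""
        vectors, model = som_setup[3], som_setup[4]
        X = vectors.to_numpy(float)
        q_trained = model.quantization_error(X)
        rng = np.random.default_rng(child_seed(23, "baseline"))
        random_cells = rng.integers(0, 100, size=len(X))
        q_random = 0.0
        for c in range(100):
            members = X[random_cells == c]
            if len(members):
                q_random += np.linalg.norm(
                    members - members.mean(axis=0), axis=1).sum()
        q_random /= len(X)
        assert q_trained < q_random

    def test_identical_rows_map_to_one_cell(self):
        data = pd.DataFrame(np.tile([1.0, 2.0, 3.0], (40, 1)),
                            index=[f"m{i}" for i in range(40)])
        model = bm.train_som(data, bm.SomParams(presentations=500, seed=1))
        assert model.assignment.nunique() == 1

    def test_non_finite_rejected(self):
        data = pd.DataFrame([[1.0, np.nan]], index=["m"])
        with pytest.raises(ValueError):
            bm.train_som(data)


class TestCellHeatmap:
    def test_all_zero_effects_flat_map(self, som_setup):
        model = som_setup[4]
        effect = pd.Series(0.0, index=model.assignment.index)
        heat = bm.cell_heatmap(model, effect)
        assert np.nanmax(np.abs(heat)) == 0.0

    def test_empty_cell_is_nan_not_zero(self, som_setup):
        model = som_setup[4]
        # score only the members of cell 0: all other cells must be nan
        members = model.members(0)
        effect = pd.Series(1.0, index=members)
        heat = bm.cell_heatmap(model, effect)
        assert heat[0] == pytest.approx(1.0)
        assert np.isnan(np.delete(heat, 0)).all()


class TestClusterBiomarkerSets:
    def test_duplicated_condition_merges_first_at_zero(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(100, 3))
        vectors = pd.DataFrame(base, columns=["a", "b", "c"])
        vectors["a_copy"] = vectors["a"]
        linkage = bm.cluster_biomarker_sets(vectors)
        assert linkage[0, 2] == pytest.approx(0.0)
        merged = {int(linkage[0, 0]), int(linkage[0, 1])}
        assert merged == {0, 3}  # columns a and a_copy

    def test_disease_dominant_structure_clusters_by_disease(self):
        """With disease effects much larger than their age modulation, the
        12 condition vectors cluster into the 4 diseases."""
        expr, meta, _ = bm.simulate_cohort(
            n_samples=1200, n_mirnas=600, seed=29,
            fractions={"disease_only": 0.4, "age_up_linear": 0.05,
                       "age_down_linear": 0.05},
            effect_sizes={"disease_d": 1.2, "disease_decay": 0.1})
        vectors = bm.biomarker_vectors(expr, meta, top_n=600)
        model = bm.train_som(vectors, bm.SomParams(seed=29))
        cell_vectors = pd.DataFrame(
            {c: np.nan_to_num(bm.cell_heatmap(model, vectors[c]))
             for c in vectors.columns})
        linkage = bm.cluster_biomarker_sets(cell_vectors)
        labels = hierarchy.fcluster(linkage, t=4, criterion="maxclust")
        by_disease = {}
        for cond, lab in zip(cell_vectors.columns, labels):
            by_disease.setdefault(cond.split("_")[0], set()).add(lab)
        # each disease's three strata fall into a single flat cluster
        assert all(len(v) == 1 for v in by_disease.values())

    def test_requires_three_conditions(self):
        with pytest.raises(ValueError):
            bm.cluster_biomarker_sets(pd.DataFrame({"a": [1.0], "b": [2.0]}))
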