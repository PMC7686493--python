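"""Core-network construction: trajectories, quantile selection, the filter
cascade against a brute-force oracle, and planted-regulation recovery."""

import numpy as np
import pandas as pd
import pytest

import bloodmir as bm
from bloodmir.datatypes import InteractionTable
from bloodmir.network import trajectory_spearman, window_trajectory
from bloodmir.stats import spearman_vs_vector


def brute_force_core(interactions, mirna_set, protein_set, mirna_traj,
                     protein_traj, min_targeting=9, rho_min=0.6):
    """Single-pass reference filter over all triples, built on plain dicts."""
    strong = [(r["mirna_id"], r["gene_id"])
              for _, r in interactions.table.iterrows()
              if r["evidence"] == "strong"
              and r["mirna_id"] in set(mirna_set)
              and r["gene_id"] in set(protein_set)]
    strong = sorted(set(strong))
    per_protein = {}
    for m, g in strong:
        per_protein.setdefault(g, set()).add(m)
    kept = []
    for m, g in strong:
        if len(per_protein[g]) < min_targeting:
            continue
        a, b = mirna_traj.loc[m], protein_traj.loc[g]
        rho = trajectory_spearman(a, b)
        if np.isfinite(rho) and abs(rho) >= rho_min:
            kept.append((m, g))
    return set(kept)


class TestWindowTrajectory:
    def test_constant_values_constant_trajectory(self):
        ages = np.arange(30, 80)
        traj = window_trajectory(np.full(50, 2.5), ages)
        assert len(traj) == 40
        assert (traj == 2.5).all()

    def test_linear_values_linear_in_midpoint(self):
        ages = np.arange(30, 80)
        traj = window_trajectory(2.0 * ages, ages)
        mids = np.array(traj.index, dtype=float) + 4.5
        assert traj.to_numpy() == pytest.approx(2.0 * mids)

    def test_empty_window_is_missing(self):
        ages = np.array([60, 61, 62, 63])
        traj = window_trajectory(np.ones(4), ages)
        assert np.isnan(traj[30])
        assert traj[55] == 1.0


class TestDirectionQuantiles:
    def test_exact_counts(self):
        mir = pd.Series(np.linspace(-1, 1, 100), index=[f"m{i:03d}" for i in range(100)])
        prot = pd.Series(np.linspace(-1, 1, 60), index=[f"p{i:03d}" for i in range(60)])
        msel, psel = bm.direction_quantiles(mir, prot, q=0.05)
        assert len(msel) == 5 and len(psel) == 3
        assert set(msel) == set(mir.nsmallest(5).index)
        assert set(psel) == set(prot.nlargest(3).index)

    def test_ties_broken_deterministically(self):
        mir = pd.Series(0.0, index=["b", "a", "c", "d"])
        prot = pd.Series(0.0, index=["q", "p"])
        m1 = bm.direction_quantiles(mir, prot, q=0.5)
        m2 = bm.direction_quantiles(mir.sample(frac=1, random_state=1), prot, q=0.5)
        assert m1 == m2

    def test_bad_quantile_rejected(self):
        s = pd.Series([0.1], index=["m"])
        with pytest.raises(ValueError):
            bm.direction_quantiles(s, s, q=0.7)

    def test_planted_down_mirnas_dominate_bottom_quantile(self, recovery_cohort):
        expr, meta, truth = recovery_cohort
        sc, _ = spearman_vs_vector(expr.values.to_numpy(float),
                                   meta.ages.to_numpy(float))
        sc = pd.Series(sc, index=expr.feature_ids)
        msel, _ = bm.direction_quantiles(sc, sc, q=0.05)
        down = set(truth.mirnas_of_class("age_down_linear"))
        assert len(set(msel) & down) / len(msel) >= 0.95


def random_instance(seed):
    """A random small instance for oracle equivalence."""
    rng = np.random.default_rng(seed)
    n_m, n_p = rng.integers(5, 26), rng.integers(3, 25)
    mirnas = [f"m{i}" for i in range(n_m)]
    proteins = [f"p{i}" for i in range(n_p)]
    rows = []
    for m in mirnas:
        for p in proteins:
            if rng.random() < 0.4:
                rows.append({"mirna_id": m, "gene_id": p,
                             "evidence": str(rng.choice(
                                 ["strong", "weak", "predicted"],
                                 p=[0.6, 0.2, 0.2]))})
    if not rows:
        rows.append({"mirna_id": mirnas[0], "gene_id": proteins[0],
                     "evidence": "strong"})
    inter = InteractionTable(pd.DataFrame(rows).drop_duplicates())
    starts = list(range(30, 70))
    mt = pd.DataFrame(rng.normal(size=(n_m, 40)).cumsum(axis=1),
                      index=mirnas, columns=starts)
    pt = pd.DataFrame(rng.normal(size=(n_p, 40)).cumsum(axis=1),
                      index=proteins, columns=starts)
    m_set = list(rng.choice(mirnas, size=max(2, n_m // 2), replace=False))
    p_set = list(rng.choice(proteins, size=max(2, n_p // 2), replace=False))
    min_t = int(rng.integers(1, 5))
    return inter, m_set, p_set, mt, pt, min_t


class TestBuildCoreNetwork:
    def test_targeting_filter_boundary(self):
        """A protein targeted by 9 candidate miRNAs survives; 8 does not."""
        starts = list(range(30, 70))
        t = np.linspace(0, 1, 40)
        mirnas = [f"m{i}" for i in range(9)]
        mt = pd.DataFrame(np.tile(-t, (9, 1)), index=mirnas, columns=starts)
        pt = pd.DataFrame([t, t], index=["hub9", "hub8"], columns=starts)
        rows = [{"mirna_id": m, "gene_id": "hub9", "evidence": "strong"}
                for m in mirnas]
        rows += [{"mirna_id": m, "gene_id": "hub8", "evidence": "strong"}
                 for m in mirnas[:8]]
        inter = InteractionTable(pd.DataFrame(rows))
        core = bm.build_core_network(inter, mirnas, ["hub9", "hub8"], mt, pt)
        assert set(core.edges["protein"]) == {"hub9"}
        loose = bm.build_core_network(inter, mirnas, ["hub9", "hub8"], mt, pt,
                                      stringent=False)
        assert set(loose.edges["protein"]) == {"hub9", "hub8"}

    def test_impossible_rho_threshold_empty(self, recovery_cohort):
        expr, meta, truth = recovery_cohort
        prot, inter, _ = bm.simulate_proteins_and_interactions(
            expr, meta, truth, n_proteins=100, seed=1)
        mt = bm.window_trajectories(expr, meta)
        pt = bm.window_trajectories(prot, meta)
        core = bm.build_core_network(inter, expr.feature_ids,
                                     prot.feature_ids, mt, pt, rho_min=1.01)
        assert len(core.edges) == 0
        assert bm.components(core) == []

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_on_random_instances(self, seed):
        inter, m_set, p_set, mt, pt, min_t = random_instance(seed)
        core = bm.build_core_network(inter, m_set, p_set, mt, pt,
                                     min_targeting=min_t)
        got = {(r["mirna"], r["protein"]) for _, r in core.edges.iterrows()}
        ref = brute_force_core(inter, m_set, p_set, mt, pt, min_targeting=min_t)
        assert got == ref

    def test_monotone_in_thresholds(self):
        inter, m_set, p_set, mt, pt, _ = random_instance(99)
        edges = {}
        for rho_min in (0.0, 0.4, 0.8):
            for min_t in (1, 2, 4):
                core = bm.build_core_network(inter, m_set, p_set, mt, pt,
                                             min_targeting=min_t,
                                             rho_min=rho_min)
                edges[(rho_min, min_t)] = {
                    (r["mirna"], r["protein"])
                    for _, r in core.edges.iterrows()}
        for (r1, t1), e1 in edges.items():
            for (r2, t2), e2 in edges.items():
                if r1 <= r2 and t1 <= t2:
                    assert e2 <= e1

    def test_planted_regulations_recovered(self, recovery_cohort):
        expr, meta, truth = recovery_cohort
        prot, inter, ledger = bm.simulate_proteins_and_interactions(
            expr, meta, truth, seed=2)
        ages = meta.ages.to_numpy(float)
        sc_m = pd.Series(spearman_vs_vector(expr.values.to_numpy(float),
                                            ages)[0], index=expr.feature_ids)
        sc_p = pd.Series(spearman_vs_vector(prot.values.to_numpy(float),
                                            ages)[0], index=prot.feature_ids)
        m_set, p_set = bm.direction_quantiles(sc_m, sc_p, q=0.05)
        core = bm.build_core_network(inter, m_set, p_set,
                                     bm.window_trajectories(expr, meta),
                                     bm.window_trajectories(prot, meta))
        got = {(r["mirna"], r["protein"]) for _, r in core.edges.iterrows()}
        true = set(map(tuple, ledger.true_regulations))
        tp = len(got & true)
        assert tp / max(len(got), 1) >= 0.8   # precision
        assert tp / len(true) >= 0.8          # recall
        comps = bm.components(core)
        assert sum(c["size"] for c in comps) == core.graph.number_of_nodes()
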