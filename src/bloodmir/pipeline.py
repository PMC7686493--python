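"""End-to-end orchestration: synthetic cohort -> all analysis stages.

``run_all`` executes simulate, associate (with overlap and sex
concordance), nonlinearity screening, arm-shift detection, sliding-window
effect sizes, SOM biomarkers, enrichment, deconvolution, the core network
and cluster trajectories, writing deterministic JSON/TSV artifacts to the
output directory.  Every stage is also independently callable with the
same artifacts the orchestrator passes.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import armshift as armshift_mod
from . import deconvolution as deconv_mod
from . import enrichment as enrich_mod
from . import network as network_mod
from . import nonlinearity as nl_mod
from . import som as som_mod
from . import trajectories as traj_mod
from . import windows as windows_mod
from .association import associate, overlap_test, sex_stratified_concordance
from .datatypes import records_to_frame
from .io import (write_gmt, write_interactions, write_json, write_matrix,
                 write_metadata, write_pair_table, write_presence)
from .simulate import (child_seed, simulate_arm_pairs, simulate_cohort,
                       simulate_compound_presence,
                       simulate_proteins_and_interactions)

log = logging.getLogger("bloodmir")


@dataclass
class PipelineConfig:
    """All thresholds and sizes of the pipeline, with the study defaults."""

    seed: int = 0
    out_dir: str = "bloodmir_out"
    # synthetic cohort
    n_samples: int = 800
    n_mirnas: int = 1000
    noise_sd: float = 1.0
    age_range: tuple[int, int] = (30, 79)
    n_arm_pairs: int = 100
    n_arm_switches: int = 10
    switch_magnitude: float = 0.35
    n_proteins: int = 500
    n_true_regulations: int = 36
    coupling: float = -1.0
    decoy_count: int = 300
    # stage thresholds
    alpha: float = 0.05
    dc_threshold: float = 0.02
    spline_df: int = 8
    arm_sc_min: float = 0.2
    arm_p_max: float = 0.05
    arm_range_min: float = 0.2
    window_span: int = 10
    window_start: int = 30
    window_last_start: int = 70
    window_min_n: int = 20
    d_threshold: float = 0.5
    som_top_n: int = 801
    som_presentations: int = 10000
    som_lr_start: float = 0.05
    som_lr_end: float = 0.01
    network_quantile: float = 0.05
    network_min_targeting: int = 9
    network_rho_min: float = 0.6
    network_window_starts: tuple[int, int] = (30, 69)

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.dc_threshold < 0:
            raise ValueError("dc_threshold must be nonnegative")
        if not (0 < self.network_quantile <= 0.5):
            raise ValueError("network_quantile must be in (0, 0.5]")
        if self.n_samples < 40:
            raise ValueError("n_samples must be >= 40")
        lo, hi = self.age_range
        if hi <= lo:
            raise ValueError("degenerate age range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.age_range = tuple(cfg.age_range)
        cfg.network_window_starts = tuple(cfg.network_window_starts)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["age_range"] = list(self.age_range)
        data["network_window_starts"] = list(self.network_window_starts)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _records_payload(records) -> list[dict]:
    frame = records_to_frame(records).reset_index()
    frame = frame.where(pd.notna(frame), None)
    return frame.to_dict(orient="records")


def run_all(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic cohort; returns the summary dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}

    def stage(name):
        log.info("stage %s", name)
        return time.perf_counter()

    timings: dict[str, float] = {}

    def done(name, t0, **counts):
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", name, timings[name])
        summary["stages"][name] = dict(counts)

    # --- simulate -----------------------------------------------------
    t0 = stage("simulate")
    expr, meta, truth = simulate_cohort(
        n_samples=config.n_samples, n_mirnas=config.n_mirnas,
        noise_sd=config.noise_sd, age_range=config.age_range, seed=config.seed)
    arm_expr, pairs, arm_truth = simulate_arm_pairs(
        config.n_arm_pairs, config.n_arm_switches, config.switch_magnitude,
        meta, seed=config.seed)
    truth.arm_switch = arm_truth.arm_switch
    proteins, interactions, prot_truth = simulate_proteins_and_interactions(
        expr, meta, truth, n_proteins=config.n_proteins,
        n_true_regulations=config.n_true_regulations,
        coupling=config.coupling, decoy_count=config.decoy_count,
        seed=config.seed)
    truth.protein_trend = prot_truth.protein_trend
    truth.true_regulations = prot_truth.true_regulations
    presence = simulate_compound_presence(expr.feature_ids, truth,
                                          seed=config.seed)
    rng = np.random.default_rng(child_seed(config.seed, "categories"))
    categories = _synthetic_categories(expr.feature_ids, truth, rng)
    write_matrix(expr, out / "expression.tsv")
    write_metadata(meta, out / "metadata.tsv")
    write_matrix(arm_expr, out / "arm_expression.tsv")
    write_pair_table(pairs, out / "arm_pairs.tsv")
    write_matrix(proteins, out / "proteins.tsv")
    write_interactions(interactions, out / "interactions.tsv")
    write_presence(presence, out / "presence.tsv")
    write_gmt(categories, out / "categories.gmt")
    write_json(truth.to_dict(), out / "truth.json")
    done("simulate", t0, n_samples=config.n_samples, n_mirnas=config.n_mirnas)

    # --- associate ----------------------------------------------------
    t0 = stage("associate")
    records = associate(expr, meta, alpha=config.alpha)
    frame = records_to_frame(records)
    n_age = int((frame["sc_p_adj"] < config.alpha).sum())
    n_sex = int((frame["sex_p_adj"] < config.alpha).sum())
    n_both = int(((frame["sc_p_adj"] < config.alpha)
                  & (frame["sex_p_adj"] < config.alpha)).sum())
    overlap = overlap_test(len(records), n_age, n_sex, n_both)
    rho, p_conc, classification = sex_stratified_concordance(expr, meta,
                                                             alpha=config.alpha)
    write_json({
        "overlap": {"table": overlap.table, "fisher_p": overlap.fisher_p,
                    "chi2_p": overlap.chi2_p, "odds_ratio": overlap.odds_ratio},
        "concordance": {"rho": rho, "p": p_conc},
        "n_age_significant": n_age, "n_sex_significant": n_sex,
    }, out / "overlap.json")
    done("associate", t0, n_age_significant=n_age, n_sex_significant=n_sex)

    # --- nonlinear ----------------------------------------------------
    t0 = stage("nonlinear")
    records = nl_mod.compute_dc(expr, meta, records)
    flags = nl_mod.flag_nonlinear(records, df=config.spline_df,
                                  threshold=config.dc_threshold,
                                  alpha=config.alpha)
    n_flagged = sum(1 for f in flags if f.flag != "none")
    write_json({"records": _records_payload(records)}, out / "associations.json")
    write_json({"flags": [vars(f) for f in flags],
                "n_flagged": n_flagged,
                "n_decreasing": sum(1 for f in flags if f.flag == "decreasing"),
                "n_increasing": sum(1 for f in flags if f.flag == "increasing")},
               out / "nonlinear.json")
    done("nonlinear", t0, n_flagged=n_flagged)

    # --- armshift -----------------------------------------------------
    t0 = stage("armshift")
    shifts = armshift_mod.detect_arm_shifts(
        arm_expr, pairs, meta, sc_min=config.arm_sc_min,
        p_max=config.arm_p_max, range_min=config.arm_range_min)
    write_json({"shifts": [vars(s) for s in shifts],
                "summary": armshift_mod.summarize(shifts)},
               out / "armshift.json")
    done("armshift", t0, n_shifts=len(shifts))

    # --- slide --------------------------------------------------------
    t0 = stage("slide")
    diseases = [g for g in ("PD", "HD", "NTLD", "LC")
                if g in set(meta.table["group"])]
    long_rows = []
    counts_by_disease = {}
    global_d = {}
    for disease in diseases:
        track = windows_mod.sliding_effect_sizes(
            expr, meta, disease, window_span=config.window_span,
            start=config.window_start, last_start=config.window_last_start,
            min_n=config.window_min_n)
        counts, _ = windows_mod.count_deregulated(track, config.d_threshold)
        counts_by_disease[disease] = {int(k): int(v) for k, v in counts.items()}
        global_d[disease] = windows_mod.global_effect_sizes(expr, meta, disease)
        for s in track.window_starts:
            col = track.d[s]
            for fid, dval in col.items():
                if np.isfinite(dval):
                    long_rows.append((disease, fid, s, dval,
                                      track.n_cases[s], track.n_controls[s]))
    pd.DataFrame(long_rows, columns=["disease", "miRNA", "window_start", "d",
                                     "n_case", "n_control"]).to_csv(
        out / "effect_sizes.tsv", sep="\t", index=False, float_format="%.10g")
    pan = windows_mod.pan_disease_summary(global_d, config.d_threshold)
    write_json({"counts": counts_by_disease,
                "pan_disease": pan.reset_index()
                .rename(columns={"index": "feature_id"})
                .to_dict(orient="records")},
               out / "slide.json")
    done("slide", t0, n_diseases=len(diseases))

    # --- som ----------------------------------------------------------
    t0 = stage("som")
    top_n = min(config.som_top_n, config.n_mirnas)
    vectors = som_mod.biomarker_vectors(expr, meta, top_n=top_n)
    params = som_mod.SomParams(presentations=config.som_presentations,
                               lr_start=config.som_lr_start,
                               lr_end=config.som_lr_end, seed=config.seed)
    model = som_mod.train_som(vectors, params)
    occupancy = model.occupancy()
    heatmaps = {cond: som_mod.cell_heatmap(model, vectors[cond]).tolist()
                for cond in vectors.columns}
    cell_vectors = pd.DataFrame(
        {cond: np.nan_to_num(som_mod.cell_heatmap(model, vectors[cond]))
         for cond in vectors.columns})
    linkage = som_mod.cluster_biomarker_sets(cell_vectors)
    newick = som_mod.linkage_to_newick(linkage, list(cell_vectors.columns))
    write_json({
        "assignment": {f: int(c) for f, c in model.assignment.items()},
        "occupancy": occupancy.tolist(),
        "mean_members": float(occupancy.mean()),
        "sd_members": float(occupancy.std(ddof=1)),
        "codebooks": np.round(model.codebooks, 8).tolist(),
        "heatmaps": heatmaps,
        "dendrogram_newick": newick,
    }, out / "som.json")
    done("som", t0, n_features=int(len(model.assignment)),
         occupied_cells=int((occupancy > 0).sum()))

    # --- enrich -------------------------------------------------------
    t0 = stage("enrich")
    sc = records_to_frame(records)["sc"].astype(float)
    sorted_ids = list(sc.sort_values(kind="mergesort").index)
    results = enrich_mod.enrich(sorted_ids, categories)
    write_json({"results": [
        {"category": r.category, "q": r.q_stat, "direction": r.direction,
         "p_exact": r.p_exact, "p_adj": r.p_adj, "n": r.n, "k": r.k}
        for r in results]}, out / "enrichment.json")
    done("enrich", t0, n_categories=len(results))

    # --- deconvolve ---------------------------------------------------
    t0 = stage("deconvolve")
    groups_sig = deconv_mod.signature_groups(presence)
    clusters = records_to_frame(records)["cluster"]
    up = list(clusters.index[clusters.isin([4, 5])])
    down = list(clusters.index[clusters.isin([1, 2])])
    bg = list(clusters.index[clusters == 3])
    enr = deconv_mod.cluster_compound_enrichment(up, down, bg, presence)
    write_json({
        "group_sizes": groups_sig.sizes(),
        "n_unassigned": len(groups_sig.unassigned),
        "specific_counts": {c: len(m) for c, m in groups_sig.specific().items()},
        "enrichment": enr.round(10).to_dict(orient="index"),
    }, out / "deconvolution.json")
    done("deconvolve", t0, n_groups=len(groups_sig.groups))

    # --- network ------------------------------------------------------
    t0 = stage("network")
    ws = range(config.network_window_starts[0],
               config.network_window_starts[1] + 1)
    mirna_traj = network_mod.window_trajectories(expr, meta, starts=ws)
    protein_traj = network_mod.window_trajectories(proteins, meta, starts=ws)
    protein_sc = pd.Series(
        *_protein_sc(proteins, meta))
    mirna_set, protein_set = network_mod.direction_quantiles(
        sc, protein_sc, q=config.network_quantile)
    core = network_mod.build_core_network(
        interactions, mirna_set, protein_set, mirna_traj, protein_traj,
        min_targeting=config.network_min_targeting,
        rho_min=config.network_rho_min)
    comps = network_mod.components(core)
    write_json({
        "edges": core.edges.to_dict(orient="records"),
        "n_mirnas": int(core.edges["mirna"].nunique()) if len(core.edges) else 0,
        "n_proteins": int(core.edges["protein"].nunique()) if len(core.edges) else 0,
        "components": comps,
    }, out / "network.json")
    network_mod.to_graphml(core, out / "core_network.graphml")
    done("network", t0, n_edges=int(len(core.edges)))

    # --- trajectories -------------------------------------------------
    t0 = stage("trajectories")
    trajs = traj_mod.cluster_trajectories(expr, meta, clusters,
                                          disease=diseases[0] if diseases else None,
                                          alpha=config.alpha)
    write_json({"clusters": [
        {"cluster": t.cluster,
         "average_first": float(t.average_curve[0]),
         "average_last": float(t.average_curve[-1]),
         "bin_marks": {f"{lo}-{hi}": m for (lo, hi), m in t.bin_marks.items()}}
        for t in trajs]}, out / "trajectories.json")
    done("trajectories", t0, n_clusters=len(trajs))

    write_json(summary, out / "summary.json")
    # timings vary run to run; they live in a separate, non-compared artifact
    write_json({"seconds": timings}, out / "timings.json")
    summary["timings"] = timings
    return summary


def _protein_sc(proteins, meta):
    from .stats import spearman_vs_vector
    meta = meta.aligned_to(proteins)
    sc, _ = spearman_vs_vector(proteins.values.to_numpy(dtype=float),
                               meta.ages.to_numpy(dtype=float))
    return sc, proteins.feature_ids


def _synthetic_categories(feature_ids, truth, rng) -> dict[str, set[str]]:
    """GMT-style categories for the enrichment stage: the planted age
    classes plus random decoy sets."""
    up = set(truth.mirnas_of_class("age_up_linear"))
    down = set(truth.mirnas_of_class("age_down_linear"))
    cats = {}
    if up:
        cats["planted_age_up"] = up
    if down:
        cats["planted_age_down"] = down
    ids = list(feature_ids)
    for j in range(3):
        size = max(5, len(ids) // 20)
        cats[f"random_{j}"] = set(rng.choice(ids, size=size, replace=False))
    return cats
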