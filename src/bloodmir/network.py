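"""miRNA -> plasma-protein core-network construction.

Both entity kinds are summarized as 10-year sliding-window mean
trajectories over 40 window starts (ages 30..69).  The core network keeps
an interaction edge only if it passes the full filter cascade:

(a) strong experimental evidence;
(b) the miRNA is among the most age-decreasing (bottom quantile);
(c) the protein is among the most age-increasing (top quantile);
(d) the protein is targeted by more than eight candidate miRNAs
    (skipped in the less stringent mode);
(e) |Spearman| of the two window trajectories >= 0.6.

Connected components of the surviving bipartite graph are reported sorted
by size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, InteractionTable, SampleMetadata
from .stats import spearman_with_p


@dataclass
class CoreNetwork:
    graph: nx.Graph
    edges: pd.DataFrame  # mirna, protein, spearman, evidence

    def components(self) -> list[list[str]]:
        comps = [sorted(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: (-len(c), c))


def window_trajectory(values, ages, starts=range(30, 70), span: int = 10) -> pd.Series:
    """Sliding-window mean of one entity's per-sample values.

    One mean per window start; windows without samples are nan and are
    excluded pairwise from trajectory correlations.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages)
    out = {}
    for s in starts:
        sel = (ages >= s) & (ages <= s + span - 1)
        out[int(s)] = float(values[sel].mean()) if sel.any() else np.nan
    return pd.Series(out)


def window_trajectories(expr: ExpressionMatrix, meta: SampleMetadata,
                        starts=range(30, 70), span: int = 10) -> pd.DataFrame:
    """All features' window trajectories (features x window starts)."""
    meta = meta.aligned_to(expr)
    ages = meta.ages.to_numpy()
    values = expr.values.to_numpy(dtype=float)
    starts = list(starts)
    cols = {}
    for s in starts:
        sel = (ages >= s) & (ages <= s + span - 1)
        cols[int(s)] = values[:, sel].mean(axis=1) if sel.any() else np.full(values.shape[0], np.nan)
    return pd.DataFrame(cols, index=expr.feature_ids)


def direction_quantiles(mirna_sc: pd.Series, protein_sc: pd.Series,
                        q: float = 0.05) -> tuple[list[str], list[str]]:
    """Bottom-q miRNAs and top-q proteins by age correlation.

    Exactly ``ceil(q * n)`` entities per side; ties broken by id so the
    selection is deterministic.
    """
    if not (0 < q <= 0.5):
        raise ValueError("q must be in (0, 0.5]")
    n_mir = int(np.ceil(q * len(mirna_sc)))
    n_prot = int(np.ceil(q * len(protein_sc)))
    mir_sorted = mirna_sc.sort_index(kind="mergesort").sort_values(kind="mergesort")
    prot_sorted = protein_sc.sort_index(kind="mergesort").sort_values(
        ascending=False, kind="mergesort")
    return list(mir_sorted.index[:n_mir]), list(prot_sorted.index[:n_prot])


def trajectory_spearman(a: pd.Series, b: pd.Series) -> float:
    """Spearman over pairwise-complete windows of two trajectories."""
    mask = a.notna() & b.notna()
    if mask.sum() < 4:
        return float("nan")
    rho, _ = spearman_with_p(a[mask].to_numpy(), b[mask].to_numpy())
    return rho


def build_core_network(
    interactions: InteractionTable,
    mirna_set,
    protein_set,
    mirna_traj: pd.DataFrame,
    protein_traj: pd.DataFrame,
    min_targeting: int = 9,
    rho_min: float = 0.6,
    stringent: bool = True,
) -> CoreNetwork:
    """Apply the five-filter cascade and return the surviving graph.

    ``stringent=False`` skips the targeting filter (d).  Filter (d) counts
    targeting miRNAs within the candidate set remaining after filters
    (a)-(c).
    """
    mirna_set = set(mirna_set)
    protein_set = set(protein_set)
    cand = interactions.strong()
    cand = cand[cand["mirna_id"].isin(mirna_set)
                & cand["gene_id"].isin(protein_set)]
    cand = cand.drop_duplicates(["mirna_id", "gene_id"])
    if stringent:
        targeting = cand.groupby("gene_id")["mirna_id"].nunique()
        keep_prot = set(targeting.index[targeting >= min_targeting])
        cand = cand[cand["gene_id"].isin(keep_prot)]
    rows = []
    for _, row in cand.iterrows():
        m, g = row["mirna_id"], row["gene_id"]
        if m not in mirna_traj.index or g not in protein_traj.index:
            continue
        rho = trajectory_spearman(mirna_traj.loc[m], protein_traj.loc[g])
        if np.isfinite(rho) and abs(rho) >= rho_min:
            rows.append({"mirna": m, "protein": g, "spearman": float(rho),
                         "evidence": "strong"})
    edges = pd.DataFrame(rows, columns=["mirna", "protein", "spearman", "evidence"])
    graph = nx.Graph()
    for _, r in edges.iterrows():
        graph.add_node(r["mirna"], kind="mirna")
        graph.add_node(r["protein"], kind="protein")
        graph.add_edge(r["mirna"], r["protein"], spearman=r["spearman"])
    return CoreNetwork(graph, edges)


def components(network: CoreNetwork) -> list[dict]:
    """Connected components with sizes, largest first."""
    out = []
    for comp in network.components():
        mirnas = [n for n in comp if network.graph.nodes[n]["kind"] == "mirna"]
        proteins = [n for n in comp if network.graph.nodes[n]["kind"] == "protein"]
        out.append({"nodes": comp, "size": len(comp),
                    "n_mirnas": len(mirnas), "n_proteins": len(proteins)})
    return out


def to_graphml(network: CoreNetwork, path) -> None:
    nx.write_graphml(network.graph, path)
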