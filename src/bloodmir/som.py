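"""Self-organizing-map biomarker analysis.

Disease biomarker vectors (Cohen's d versus healthy controls for each
disease over all patients, young patients and old patients) are mapped by
a sequential Kohonen network onto a 10 x 10 hexagonal grid.  The learning
rate decays linearly from 0.05 to 0.01 over 10,000 presentations, the
Gaussian neighborhood radius shrinks linearly over the same schedule.
Per-cell mean effect sizes give the heat-map view; condition vectors of
cell summaries are compared by complete-linkage hierarchical clustering on
Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datatypes import ExpressionMatrix, SampleMetadata
from .simulate import child_seed
from .windows import global_effect_sizes

DISEASES = ("PD", "HD", "NTLD", "LC")
STRATA = ("all", "young", "old")


@dataclass
class SomParams:
    rows: int = 10
    cols: int = 10
    presentations: int = 10000
    lr_start: float = 0.05
    lr_end: float = 0.01
    sigma_start: float = 3.0
    sigma_end: float = 0.5
    seed: int = 0


@dataclass
class SomModel:
    params: SomParams
    codebooks: np.ndarray          # (rows*cols, dim)
    positions: np.ndarray          # (rows*cols, 2) hexagonal plane coords
    assignment: pd.Series          # feature -> cell index
    feature_ids: list[str] = field(default_factory=list)

    def members(self, cell: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cell])

    def occupancy(self) -> np.ndarray:
        counts = np.zeros(self.codebooks.shape[0], dtype=int)
        for c in self.assignment:
            counts[c] += 1
        return counts

    def quantization_error(self, data: np.ndarray) -> float:
        d = np.linalg.norm(data[:, None, :] - self.codebooks[None, :, :], axis=2)
        return float(d.min(axis=1).mean())


def hex_positions(rows: int, cols: int) -> np.ndarray:
    """Plane coordinates of an odd-row-offset hexagonal grid."""
    pos = np.empty((rows * cols, 2))
    for r in range(rows):
        for c in range(cols):
            pos[r * cols + c] = (c + 0.5 * (r % 2), r * np.sqrt(3.0) / 2.0)
    return pos


def biomarker_vectors(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    young: tuple[int, int] = (30, 59),
    old: tuple[int, int] = (60, 79),
    top_n: int = 801,
    diseases=DISEASES,
) -> pd.DataFrame:
    """miRNA x condition matrix of effect sizes (disease x age stratum).

    Conditions are each disease against healthy controls over all ages,
    the young stratum and the old stratum.  Only the ``top_n`` highest
    expressed miRNAs (by median over all samples) are kept.  Conditions
    with an empty stratum are dropped with a warning.
    """
    import warnings

    medians = expr.values.median(axis=1)
    top = medians.sort_values(ascending=False, kind="mergesort").index[:top_n]
    sub = expr.subset_features(top)
    cols = {}
    for disease in diseases:
        for stratum, rng in (("all", None), ("young", young), ("old", old)):
            name = f"{disease}_{stratum}"
            try:
                cols[name] = global_effect_sizes(sub, meta, disease, age_range=rng)
            except ValueError as exc:
                warnings.warn(f"condition {name} dropped: {exc}")
    return pd.DataFrame(cols)


def train_som(data: pd.DataFrame, params: SomParams | None = None) -> SomModel:
    """Sequential Kohonen training of feature vectors on the hexagonal grid.

    Codebooks are initialized from randomly drawn data rows; each of the
    ``presentations`` steps presents one random row, moves the best
    matching unit and its Gaussian neighborhood toward it, with both the
    learning rate and the radius decaying linearly.
    """
    params = params or SomParams()
    X = data.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("SOM input must be finite")
    n, dim = X.shape
    rng = np.random.default_rng(child_seed(params.seed, "som"))
    n_cells = params.rows * params.cols
    pos = hex_positions(params.rows, params.cols)
    init_idx = rng.choice(n, size=n_cells, replace=n < n_cells)
    codebooks = X[init_idx].astype(float) + rng.normal(0, 1e-6, (n_cells, dim))
    grid_d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    T = params.presentations
    order = rng.integers(0, n, size=T)
    for t in range(T):
        frac = t / max(T - 1, 1)
        lr = params.lr_start + (params.lr_end - params.lr_start) * frac
        sigma = params.sigma_start + (params.sigma_end - params.sigma_start) * frac
        x = X[order[t]]
        bmu = int(np.argmin(((codebooks - x) ** 2).sum(axis=1)))
        h = np.exp(-grid_d2[bmu] / (2.0 * sigma * sigma))
        codebooks += (lr * h)[:, None] * (x - codebooks)
    d = np.linalg.norm(X[:, None, :] - codebooks[None, :, :], axis=2)
    assignment = pd.Series(d.argmin(axis=1), index=data.index)
    return SomModel(params, codebooks, pos, assignment, list(data.index))


def cell_heatmap(model: SomModel, effect: pd.Series) -> np.ndarray:
    """Per-cell mean of member effect sizes; empty cells are nan."""
    n_cells = model.codebooks.shape[0]
    out = np.full(n_cells, np.nan)
    grouped = effect.groupby(model.assignment.reindex(effect.index))
    for cell, mean in grouped.mean().items():
        out[int(cell)] = mean
    return out


def cluster_biomarker_sets(vectors: pd.DataFrame):
    """Complete-linkage Euclidean clustering of condition vectors.

    ``vectors`` has one column per condition (e.g. per-cell mean effect
    sizes); returns the scipy linkage matrix over columns.
    """
    if vectors.shape[1] < 3:
        raise ValueError("need at least 3 conditions")
    mat = vectors.to_numpy(dtype=float).T
    return hierarchy.linkage(mat, method="complete", metric="euclidean")


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Newick string of a scipy linkage matrix (branch lengths = heights)."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
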