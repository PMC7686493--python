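"""Per-cluster expression trajectories with 5-year case/control marks.

For each correlation cluster, every member miRNA's expression-vs-age curve
within healthy samples is smoothed with a spline (df = 3) and averaged;
disjoint 5-year age bins anchored at age 30 are marked up/down when a
two-sided Wilcoxon test of cases versus controls is significant at an
unadjusted alpha of 0.05 (the direction follows the case-control median
difference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, SampleMetadata
from .stats import smooth_spline


@dataclass
class ClusterTrajectory:
    cluster: int
    ages_grid: np.ndarray
    member_curves: pd.DataFrame      # miRNA x grid point
    average_curve: np.ndarray
    bin_marks: dict[tuple[int, int], str]  # (lo, hi) -> up | down | none


def age_bins(age_range: tuple[int, int], width: int = 5,
             anchor: int = 30) -> list[tuple[int, int]]:
    """Disjoint [lo, lo+width-1] bins tiling the age range from the anchor."""
    lo, hi = age_range
    bins = []
    s = anchor
    while s <= hi:
        bins.append((s, min(s + width - 1, hi)))
        s += width
    return bins


def cluster_trajectories(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    clusters: pd.Series,
    disease: str | None = None,
    alpha: float = 0.05,
    df: int = 3,
    n_grid: int = 50,
    min_bin_n: int = 2,
) -> list[ClusterTrajectory]:
    """Spline trajectories per cluster with per-bin case/control marks.

    Curves are fitted on healthy (HC) samples.  When ``disease`` is given,
    each 5-year bin is tested disease-vs-HC with a two-sided Wilcoxon test
    on the cluster-average expression of samples in the bin; bins lacking
    ``min_bin_n`` samples in either group are marked ``none``.
    """
    meta = meta.aligned_to(expr)
    groups = meta.table["group"]
    ages = meta.ages.to_numpy()
    hc = (groups == "HC").to_numpy()
    if hc.sum() < df + 2:
        raise ValueError("too few healthy samples to fit trajectories")
    grid = np.linspace(ages[hc].min(), ages[hc].max(), n_grid)
    bins = age_bins(meta.age_range)
    out = []
    values = expr.values.to_numpy(dtype=float)
    feat_index = {f: i for i, f in enumerate(expr.feature_ids)}
    for cl in sorted(clusters.dropna().unique()):
        members = [f for f in clusters.index[clusters == cl] if f in feat_index]
        if not members:
            continue
        curves = {}
        for f in members:
            v = values[feat_index[f]]
            spl = smooth_spline(ages[hc], v[hc], df=df)
            curves[f] = spl(grid)
        member_curves = pd.DataFrame(curves).T
        member_curves.columns = grid
        average = member_curves.to_numpy().mean(axis=0)
        marks = {}
        if disease is not None:
            is_case = (groups == disease).to_numpy()
            cluster_mean = values[[feat_index[f] for f in members]].mean(axis=0)
            for lo, hi in bins:
                in_bin = (ages >= lo) & (ages <= hi)
                case_v = cluster_mean[in_bin & is_case]
                ctrl_v = cluster_mean[in_bin & hc]
                if case_v.size < min_bin_n or ctrl_v.size < min_bin_n:
                    marks[(lo, hi)] = "none"
                    continue
                if np.ptp(np.concatenate([case_v, ctrl_v])) == 0:
                    marks[(lo, hi)] = "none"
                    continue
                p = float(stats.mannwhitneyu(case_v, ctrl_v,
                                             alternative="two-sided").pvalue)
                if p < alpha:
                    marks[(lo, hi)] = ("up" if np.median(case_v) > np.median(ctrl_v)
                                       else "down")
                else:
                    marks[(lo, hi)] = "none"
        out.append(ClusterTrajectory(int(cl), grid, member_curves, average, marks))
    return out
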