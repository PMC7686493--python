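"""Stage 1: per-miRNA sex tests, age correlations and correlation clusters.

Sex differences use the two-sided Wilcoxon Mann-Whitney test (normal
approximation with tie correction; exact enumeration for small groups),
age trends use Spearman correlation with the asymptotic-t p-value plus
Pearson correlation.  Both p-value families are Benjamini-Hochberg
adjusted across miRNAs, separately.  Each miRNA is then assigned to one of
five correlation clusters:

    1: SC < -0.2        (strongly decreasing with age)
    2: -0.2 <= SC < -0.1
    3: -0.1 <= SC <= 0.1 (unaltered)
    4: 0.1 < SC <= 0.2
    5: SC > 0.2          (strongly increasing)

Boundary values belong to the less extreme cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import AgeAssociationRecord, ExpressionMatrix, SampleMetadata
from .stats import adjust_bh, pearson_vs_vector, spearman_vs_vector, spearman_with_p

CLUSTER_BOUNDS = (-0.2, -0.1, 0.1, 0.2)


@dataclass
class OverlapResult:
    """2x2 overlap of two significant sets in a common universe."""

    both: int
    a_only: int
    b_only: int
    neither: int
    fisher_p: float
    chi2_p: float
    odds_ratio: float

    @property
    def table(self) -> list[list[int]]:
        return [[self.both, self.a_only], [self.b_only, self.neither]]


def _wilcoxon_p(values: np.ndarray, group_a: np.ndarray, group_b: np.ndarray,
                exact_max: int = 25) -> float:
    """Two-sided Mann-Whitney p; exact for small groups, else normal
    approximation with tie correction."""
    a = values[group_a]
    b = values[group_b]
    if np.ptp(values) == 0:
        return float("nan")
    method = "exact" if max(a.size, b.size) <= exact_max and not _has_ties(values) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def associate(expr: ExpressionMatrix, meta: SampleMetadata,
              alpha: float = 0.05) -> list[AgeAssociationRecord]:
    """Per-miRNA sex Wilcoxon and age Spearman/Pearson with BH adjustment.

    Single-sex cohorts leave the sex tests flagged missing (nan); constant
    miRNAs leave both families missing for that feature.
    """
    meta = meta.aligned_to(expr)
    ages = meta.ages.to_numpy(dtype=float)
    sex = meta.table["sex"].to_numpy()
    values = expr.values.to_numpy(dtype=float)
    is_m = sex == "male"
    is_f = sex == "female"
    both_sexes = is_m.sum() >= 4 and is_f.sum() >= 4

    sc, sc_p = spearman_vs_vector(values, ages)
    pc = pearson_vs_vector(values, ages)
    sex_p = np.full(len(expr.feature_ids), np.nan)
    if both_sexes:
        for i in range(values.shape[0]):
            sex_p[i] = _wilcoxon_p(values[i], is_m, is_f)

    sc_p_adj = _adjust_with_nan(sc_p)
    sex_p_adj = _adjust_with_nan(sex_p)

    records = []
    for i, fid in enumerate(expr.feature_ids):
        records.append(AgeAssociationRecord(
            feature_id=fid,
            sc=_opt(sc[i]), sc_p=_opt(sc_p[i]), sc_p_adj=_opt(sc_p_adj[i]),
            pc=_opt(pc[i]),
            sex_p=_opt(sex_p[i]), sex_p_adj=_opt(sex_p_adj[i]),
        ))
    return assign_clusters(records)


def _adjust_with_nan(p: np.ndarray) -> np.ndarray:
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = adjust_bh(p[mask])
    return out


def _opt(x: float) -> float | None:
    return None if not np.isfinite(x) else float(x)


def assign_cluster(sc: float | None) -> int | None:
    """Cluster id for one Spearman coefficient (boundaries go inward)."""
    if sc is None or not np.isfinite(sc):
        return None
    b1, b2, b3, b4 = CLUSTER_BOUNDS
    if sc < b1:
        return 1
    if sc < b2:
        return 2
    if sc <= b3:
        return 3
    if sc <= b4:
        return 4
    return 5


def assign_clusters(records: list[AgeAssociationRecord]) -> list[AgeAssociationRecord]:
    for r in records:
        r.cluster = assign_cluster(r.sc)
    return records


def overlap_test(n_universe: int, n_a: int, n_b: int, n_both: int) -> OverlapResult:
    """Fisher exact (two-sided) and Yates-corrected chi-square for the
    overlap of two significant sets in a universe of features."""
    if n_both > min(n_a, n_b):
        raise ValueError("overlap exceeds a set size")
    if n_a + n_b - n_both > n_universe:
        raise ValueError("sets exceed the universe")
    if min(n_universe, n_a, n_b, n_both) < 0:
        raise ValueError("counts must be nonnegative")
    both = n_both
    a_only = n_a - n_both
    b_only = n_b - n_both
    neither = n_universe - n_a - b_only
    table = np.array([[both, a_only], [b_only, neither]])
    odds, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    chi2 = stats.chi2_contingency(table, correction=True)
    return OverlapResult(both, a_only, b_only, neither,
                         float(fisher_p), float(chi2.pvalue), float(odds))


def sex_stratified_concordance(expr: ExpressionMatrix, meta: SampleMetadata,
                               alpha: float = 0.05):
    """Concordance of male-only vs female-only age correlations.

    Returns ``(rho, p, classification)`` where the classification maps
    each miRNA to {both, males_only, females_only, neither} by BH-adjusted
    within-sex age p-values at ``alpha``.
    """
    meta = meta.aligned_to(expr)
    out = {}
    for sex in ("male", "female"):
        ids = meta.table.index[meta.table["sex"] == sex]
        if len(ids) < 10:
            raise ValueError(f"need >= 10 {sex} samples")
        sub = expr.subset_samples(ids)
        ages = meta.table.loc[ids, "age"].to_numpy(dtype=float)
        sc, p = spearman_vs_vector(sub.values.to_numpy(dtype=float), ages)
        out[sex] = (sc, _adjust_with_nan(p))
    sc_m, adj_m = out["male"]
    sc_f, adj_f = out["female"]
    mask = np.isfinite(sc_m) & np.isfinite(sc_f)
    rho, p = spearman_with_p(sc_m[mask], sc_f[mask])
    sig_m = adj_m < alpha
    sig_f = adj_f < alpha
    classification = {}
    for i, fid in enumerate(expr.feature_ids):
        if sig_m[i] and sig_f[i]:
            classification[fid] = "both"
        elif sig_m[i]:
            classification[fid] = "males_only"
        elif sig_f[i]:
            classification[fid] = "females_only"
        else:
            classification[fid] = "neither"
    return rho, p, classification
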