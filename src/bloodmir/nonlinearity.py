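"""Stage 2: distance-correlation screening for nonlinear age trends.

For every miRNA the Székely sample distance correlation (dc) against age is
computed and compared with the Spearman coefficient (sc).  Across all
miRNAs, dc is regressed on sc with a smoothing spline (df = 8); a miRNA
whose (sc, dc) point lies above the spline by more than a Euclidean
distance threshold (default 0.02) and that is altered with age (BH-adjusted
age p < alpha) is flagged as nonlinear, decreasing if sc < 0 and increasing
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AgeAssociationRecord, ExpressionMatrix, SampleMetadata
from .stats import smooth_spline


@dataclass
class NonlinearFlag:
    feature_id: str
    sc: float
    dc: float
    residual_distance: float
    flag: str  # none | increasing | decreasing


def _centered_distances(v: np.ndarray) -> np.ndarray:
    """Double-centered pairwise Euclidean distance matrix of a 1-d sample."""
    d = np.abs(v[:, None] - v[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_correlation(x, y) -> float:
    """Székely sample distance correlation, in [0, 1].

    Symmetric in its arguments and invariant to shifting/scaling of either
    variable; constant input yields 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    A = _centered_distances(x)
    B = _centered_distances(y)
    n2 = x.size**2
    dcov2 = float((A * B).sum()) / n2
    dvarx = float((A * A).sum()) / n2
    dvary = float((B * B).sum()) / n2
    denom = np.sqrt(dvarx * dvary)
    if denom <= 0 or dcov2 <= 0:
        return 0.0
    return float(min(1.0, np.sqrt(dcov2 / denom)))


def distance_correlation_vs_vector(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise distance correlation of a matrix against one vector.

    The double-centered distance matrix of ``y`` is computed once and
    shared across rows.
    """
    y = np.asarray(y, dtype=float)
    B = _centered_distances(y)
    dvary = float((B * B).sum()) / y.size**2
    n2 = y.size**2
    out = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        v = values[i]
        if np.ptp(v) == 0 or dvary <= 0:
            out[i] = 0.0
            continue
        A = _centered_distances(v)
        dcov2 = float((A * B).sum()) / n2
        dvarx = float((A * A).sum()) / n2
        denom = np.sqrt(dvarx * dvary)
        out[i] = float(min(1.0, np.sqrt(dcov2 / denom))) if denom > 0 and dcov2 > 0 else 0.0
    return out


def compute_dc(expr: ExpressionMatrix, meta: SampleMetadata,
               records: list[AgeAssociationRecord]) -> list[AgeAssociationRecord]:
    """Fill the ``dc`` field of association records from the matrix."""
    meta = meta.aligned_to(expr)
    ages = meta.ages.to_numpy(dtype=float)
    dc = distance_correlation_vs_vector(expr.values.to_numpy(dtype=float), ages)
    lookup = dict(zip(expr.feature_ids, dc))
    for r in records:
        r.dc = float(lookup[r.feature_id])
    return records


def _min_distance_to_curve(points: np.ndarray, curve: np.ndarray) -> np.ndarray:
    """Min Euclidean distance of each (sc, dc) point to a sampled curve."""
    diff = points[:, None, :] - curve[None, :, :]
    return np.sqrt((diff**2).sum(axis=2)).min(axis=1)


def flag_nonlinear(records: list[AgeAssociationRecord], df: int = 8,
                   threshold: float = 0.02, alpha: float = 0.05,
                   n_curve: int = 512, robust_iter: int = 2) -> list[NonlinearFlag]:
    """Flag miRNAs whose dc exceeds what their sc predicts.

    The trend spline of dc vs sc is fitted over *all* records with
    ``robust_iter`` rounds of bisquare reweighting, so the curve tracks
    the bulk sc-dc relation rather than the excess-dc outliers it is meant
    to expose.  Flags are restricted to records altered with age
    (BH-adjusted age p < ``alpha``), must lie above the spline, and must be
    farther than ``threshold`` (strictly greater) from the densely sampled
    curve.  Also updates each record's ``nonlinear`` field.
    """
    usable = [r for r in records if r.sc is not None and r.dc is not None]
    if len(usable) < 20:
        raise ValueError("need at least 20 records with sc and dc")
    if len(usable) < df + 1:
        raise ValueError(f"need more than df={df} records")
    sc = np.array([r.sc for r in usable])
    dc = np.array([r.dc for r in usable])
    spline = smooth_spline(sc, dc, df=df)
    for _ in range(robust_iter):
        resid = dc - spline(sc)
        scale = 6.0 * np.median(np.abs(resid - np.median(resid))) + 1e-12
        w = np.clip(1.0 - (resid / scale) ** 2, 0.0, None) ** 2
        spline = smooth_spline(sc, dc, df=df, weights=w)
    grid = np.linspace(sc.min(), sc.max(), n_curve)
    curve = np.column_stack([grid, spline(grid)])
    dist = _min_distance_to_curve(np.column_stack([sc, dc]), curve)
    above = dc > spline(sc)
    flags = []
    for r, d_i, above_i in zip(usable, dist, above):
        altered = r.sc_p_adj is not None and r.sc_p_adj < alpha
        flagged = altered and above_i and d_i > threshold
        if flagged:
            flag = "decreasing" if r.sc < 0 else "increasing"
        else:
            flag = "none"
        r.nonlinear = flag
        flags.append(NonlinearFlag(r.feature_id, float(r.sc), float(r.dc),
                                   float(d_i), flag))
    return flags
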