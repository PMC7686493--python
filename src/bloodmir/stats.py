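"""Shared statistical utilities.

Benjamini-Hochberg step-up adjustment, Spearman correlation with the
asymptotic-t p-value (the convention of R's ``cor.test``), Cohen's d with
pooled standard deviation, and least-squares B-spline smoothing with a
degrees-of-freedom parameter.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import interpolate, stats


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Output preserves input order; values are monotone-enforced from the
    largest rank down and capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def spearman_with_p(x, y) -> tuple[float, float]:
    """Spearman rho with its two-sided asymptotic-t p-value.

    Ties are handled by average ranks; rho is the Pearson correlation of the
    rank vectors and p comes from ``t = rho * sqrt((n-2) / (1-rho^2))`` on
    n-2 degrees of freedom.  A constant input makes rho undefined and
    returns ``(nan, nan)`` rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    rho = float(rx @ ry) / denom
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return (rho, 0.0)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return (rho, float(p))


def spearman_vs_vector(values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise ``spearman_with_p`` of a matrix against one vector.

    Vectorized over rows: ranks are computed per row, rho by centered dot
    products, p by the same asymptotic-t formula.  Constant rows yield nan.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if values.shape[1] != n:
        raise ValueError("matrix columns must match vector length")
    ry = stats.rankdata(y)
    ry = ry - ry.mean()
    ry_ss = float(ry @ ry)
    rx = stats.rankdata(values, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    rx_ss = np.einsum("ij,ij->i", rx, rx)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ ry) / np.sqrt(rx_ss * ry_ss)
    rho = np.clip(rho, -1.0, 1.0)
    const = np.ptp(values, axis=1) == 0
    rho[const] = np.nan
    if ry_ss == 0:
        rho[:] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = np.where(np.abs(rho) == 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    p[np.isnan(rho)] = np.nan
    return rho, p


def pearson_vs_vector(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of a matrix against one vector."""
    values = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = values - values.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / np.sqrt(np.einsum("ij,ij->i", xc, xc) * float(yc @ yc))
    r = np.clip(r, -1.0, 1.0)
    r[np.ptp(values, axis=1) == 0] = np.nan
    return r


def cohens_d(case_values, control_values) -> float:
    """Cohen's d with pooled sample SD; positive means up in cases.

    ``nan`` is returned when the pooled SD is zero (both groups constant).
    """
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    n1, n2 = a.size, b.size
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / math.sqrt(s2))


def cohens_d_rows(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Row-wise Cohen's d for matrices (features x samples per group)."""
    n1 = case.shape[1]
    n2 = control.shape[1]
    v1 = case.var(axis=1, ddof=1)
    v2 = control.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (case.mean(axis=1) - control.mean(axis=1)) / np.sqrt(s2)
    d[s2 == 0] = np.nan
    return d


def smooth_spline(x, y, df: int = 8, weights=None):
    """Least-squares B-spline fit with ``df`` coefficients.

    A regression-spline stand-in for a smoothing spline with the given
    effective degrees of freedom: cubic basis with ``df - 4`` interior knots
    placed at quantiles of ``x`` (quadratic basis when df == 3).  Optional
    ``weights`` give a weighted fit.  Returns a callable evaluating the
    fitted curve.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if df < 3:
        raise ValueError("df must be >= 3")
    if x.size < df + 1:
        raise ValueError(f"need at least {df + 1} points for df={df}")
    k = 3 if df >= 4 else 2
    n_interior = df - (k + 1)
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        mean = float(y.mean())
        return lambda t: np.full_like(np.asarray(t, dtype=float), mean)
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
        # keep knots strictly inside and distinct
        interior = np.clip(interior, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
        interior = np.unique(interior)
    else:
        interior = np.array([])
    t = np.concatenate([[lo] * (k + 1), interior, [hi] * (k + 1)])
    xc = np.clip(x, lo, hi)
    order = np.argsort(xc, kind="mergesort")
    design = interpolate.BSpline.design_matrix(xc[order], t, k).toarray()
    ys = y[order]
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float)[order])
        coefs, *_ = np.linalg.lstsq(design * w[:, None], ys * w, rcond=None)
    else:
        coefs, *_ = np.linalg.lstsq(design, ys, rcond=None)
    spline = interpolate.BSpline(t, coefs, k, extrapolate=True)

    def evaluate(tt):
        tt = np.clip(np.asarray(tt, dtype=float), lo, hi)
        return spline(tt)

    return evaluate
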