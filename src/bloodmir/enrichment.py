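"""Running-sum category enrichment over an age-sorted miRNA list.

The miRNA list is sorted by increasing correlation with age and walked left
to right; category members step the sum up by (n - k), non-members step it
down by k, so every curve closes at zero.  The statistic is the maximum
absolute partial sum.  Its p-value is exact: a dynamic program counts, with
integer arithmetic, the arrangements of k hits among n positions whose
partial sums stay strictly below the observed statistic.  A curve whose
extremum is negative ("V" shape) has its members concentrated on the right
of the list, i.e. among miRNAs increasing with age; a positive extremum
("pyramid") marks an age-decreasing category.

Over-representation analysis (upper-tail hypergeometric with BH adjustment)
is provided for unordered hit sets, e.g. tissue-style annotation of a
flagged subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import stats

from .stats import adjust_bh


@dataclass
class RunningSumResult:
    category: str
    curve: np.ndarray
    q_stat: int
    direction: str  # age_increasing | age_decreasing
    p_exact: float | None = None
    p_adj: float | None = None
    n: int = 0
    k: int = 0


def running_sum(sorted_ids, category, name: str = "") -> RunningSumResult:
    """Running-sum curve and statistic for one category.

    ``sorted_ids`` is the full ranked list (increasing age correlation);
    ``category`` a set of member ids.  Requires 0 < k < n members present.
    """
    ids = list(sorted_ids)
    n = len(ids)
    members = set(category) & set(ids)
    k = len(members)
    if k == 0 or k == n:
        raise ValueError(f"category {name!r} has no contrast: k={k} of n={n}")
    hit = np.fromiter((i in members for i in ids), dtype=bool, count=n)
    steps = np.where(hit, n - k, -k)
    curve = np.cumsum(steps)
    q = int(np.max(np.abs(curve)))
    extremum = curve[int(np.argmax(np.abs(curve)))]
    direction = "age_increasing" if extremum < 0 else "age_decreasing"
    return RunningSumResult(name, curve, q, direction, n=n, k=k)


def exact_pvalue(n: int, k: int, q: int) -> float:
    """Exact P(max |partial sum| >= q) for k hits uniformly placed among n.

    The partial sum after i steps with h hits equals ``h*n - i*k`` (hit
    step n-k, miss step -k), so whether a path has stayed strictly inside
    (-q, q) depends only on the lattice point (i, h).  Counting surviving
    paths is a Pascal-style DP over h with exact integers; the p-value is
    ``1 - surviving / C(n, k)``.
    """
    if not (0 < k < n):
        raise ValueError("require 0 < k < n")
    if q <= 0:
        raise ValueError("require q > 0")
    # f[h] = number of prefixes with i steps, h hits, all |partial sums| < q
    f = [0] * (k + 1)
    f[0] = 1
    for i in range(1, n + 1):
        for h in range(min(k, i), -1, -1):
            tot = f[h] if i - 1 >= h else 0
            if h > 0:
                tot += f[h - 1]
            if tot and abs(h * n - i * k) >= q:
                tot = 0
            f[h] = tot
    surviving = f[k]
    total = comb(n, k)
    return float((total - surviving) / total)


def permutation_curves(n: int, k: int, reps: int, seed: int) -> list[np.ndarray]:
    """Random-arrangement running-sum curves (plotting / Monte-Carlo check)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not (0 < k < n):
        raise ValueError("require 0 < k < n")
    rng = np.random.default_rng(seed)
    curves = []
    base = np.full(n, -k, dtype=np.int64)
    for _ in range(reps):
        steps = base.copy()
        steps[rng.choice(n, size=k, replace=False)] = n - k
        curves.append(np.cumsum(steps))
    return curves


def enrich(sorted_ids, categories: dict[str, set[str]]) -> list[RunningSumResult]:
    """Running-sum enrichment with exact p-values, BH-adjusted across
    categories.  Categories with no contrast (k = 0 or k = n) are skipped."""
    results = []
    for name, members in categories.items():
        k = len(set(members) & set(sorted_ids))
        if k == 0 or k == len(list(sorted_ids)):
            continue
        res = running_sum(sorted_ids, members, name=name)
        res.p_exact = exact_pvalue(res.n, res.k, res.q_stat)
        results.append(res)
    if results:
        adj = adjust_bh([r.p_exact for r in results])
        for r, a in zip(results, adj):
            r.p_adj = float(a)
    return results


def ora_hypergeometric(hits, categories: dict[str, set[str]], universe):
    """Upper-tail hypergeometric over-representation per category.

    Returns a list of dicts (category, overlap, p, p_adj).  ``hits`` must be
    a subset of ``universe``; category members outside the universe are
    ignored.
    """
    universe = set(universe)
    hits = set(hits)
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    M = len(universe)
    N = len(hits)
    out = []
    for name, members in categories.items():
        K = len(set(members) & universe)
        if K == 0:
            continue
        overlap = len(set(members) & hits)
        p = float(stats.hypergeom.sf(overlap - 1, M, K, N))
        out.append({"category": name, "overlap": overlap, "p": min(p, 1.0)})
    if out:
        adj = adjust_bh([r["p"] for r in out])
        for r, a in zip(out, adj):
            r["p_adj"] = float(a)
    return out
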