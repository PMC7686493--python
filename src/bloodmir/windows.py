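"""Sliding-window case-control effect sizes (Cohen's d).

Each disease group is compared with healthy controls inside 10-year age
windows shifted by one year (starts 30..70, so the last window covers ages
70-79 inclusive).  Effect sizes are only computed where at least 20 cases
and 20 controls fall in the window; other windows stay missing.  Counting
miRNAs with |d| above 0.5 per window yields the deregulation track of the
disease.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, SampleMetadata
from .stats import cohens_d, cohens_d_rows, smooth_spline

__all__ = ["cohens_d", "EffectSizeTrack", "sliding_effect_sizes",
           "count_deregulated", "pan_disease_summary"]


@dataclass
class EffectSizeTrack:
    disease: str
    window_starts: list[int]
    d: pd.DataFrame  # miRNA x window_start, nan where ineligible
    n_cases: dict[int, int] = field(default_factory=dict)
    n_controls: dict[int, int] = field(default_factory=dict)


def sliding_effect_sizes(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    disease: str,
    window_span: int = 10,
    step: int = 1,
    start: int = 30,
    last_start: int = 70,
    min_n: int = 20,
    control_group: str = "HC",
) -> EffectSizeTrack:
    """Per-miRNA Cohen's d (disease vs HC) in each age window."""
    meta = meta.aligned_to(expr)
    groups = meta.table["group"]
    if disease not in set(groups):
        raise ValueError(f"group {disease!r} absent from metadata")
    ages = meta.ages.to_numpy()
    is_case = (groups == disease).to_numpy()
    is_ctrl = (groups == control_group).to_numpy()
    values = expr.values.to_numpy(dtype=float)
    starts = list(range(start, last_start + 1, step))
    d = pd.DataFrame(np.nan, index=expr.feature_ids, columns=starts)
    n_cases, n_controls = {}, {}
    for s in starts:
        in_win = (ages >= s) & (ages <= s + window_span - 1)
        case_idx = in_win & is_case
        ctrl_idx = in_win & is_ctrl
        n_cases[s] = int(case_idx.sum())
        n_controls[s] = int(ctrl_idx.sum())
        if n_cases[s] >= min_n and n_controls[s] >= min_n:
            d[s] = cohens_d_rows(values[:, case_idx], values[:, ctrl_idx])
    return EffectSizeTrack(disease, starts, d, n_cases, n_controls)


def count_deregulated(track: EffectSizeTrack, d_threshold: float = 0.5,
                      spline_df: int = 8):
    """Number of miRNAs with |d| above the threshold per eligible window.

    Returns ``(counts, spline)``: a Series over eligible window starts and
    a smoothing-spline fit of counts against window midpoints (None when
    there are too few windows to fit).
    """
    if track.d.empty:
        raise ValueError("empty effect-size track")
    eligible = [s for s in track.window_starts
                if not track.d[s].isna().all()]
    counts = pd.Series(
        {s: int((track.d[s].abs() > d_threshold).sum()) for s in eligible})
    spline = None
    if len(eligible) >= spline_df + 1:
        mids = np.array(eligible, dtype=float) + 4.5
        spline = smooth_spline(mids, counts.to_numpy(dtype=float), df=spline_df)
    return counts, spline


def pan_disease_summary(tracks: dict[str, pd.Series],
                        d_threshold: float = 0.5) -> pd.DataFrame:
    """Per-miRNA pan-disease relevance from whole-cohort effect sizes.

    ``tracks`` maps disease -> per-miRNA global Cohen's d Series.  Returns a
    frame with ``n_diseases_relevant`` (count of diseases with |d| above the
    threshold) and ``mean_abs_d`` across diseases.
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 diseases")
    frame = pd.DataFrame(tracks)
    return pd.DataFrame({
        "n_diseases_relevant": (frame.abs() > d_threshold).sum(axis=1).astype(int),
        "mean_abs_d": frame.abs().mean(axis=1),
    })


def global_effect_sizes(expr: ExpressionMatrix, meta: SampleMetadata,
                        disease: str, control_group: str = "HC",
                        age_range: tuple[int, int] | None = None) -> pd.Series:
    """Whole-cohort (or age-stratum) Cohen's d per miRNA, disease vs HC."""
    meta = meta.aligned_to(expr)
    groups = meta.table["group"]
    ages = meta.ages.to_numpy()
    sel = np.ones(len(ages), dtype=bool)
    if age_range is not None:
        sel = (ages >= age_range[0]) & (ages <= age_range[1])
    case = (groups == disease).to_numpy() & sel
    ctrl = (groups == control_group).to_numpy() & sel
    if case.sum() < 2 or ctrl.sum() < 2:
        raise ValueError(f"fewer than 2 cases or controls for {disease!r}")
    values = expr.values.to_numpy(dtype=float)
    d = cohens_d_rows(values[:, case], values[:, ctrl])
    return pd.Series(d, index=expr.feature_ids)
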