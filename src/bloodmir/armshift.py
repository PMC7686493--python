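"""Detection of age-associated 5'/3' arm-usage shifts.

For each precursor the per-sample 5' fraction is computed on the linear
scale; a pair is reported as an arm shift when all four criteria hold:

1. |Spearman(fraction, age)| > 0.2
2. its asymptotic-t p-value <= 0.05
3. max - min of the per-sample 5' fraction > 0.2
4. the 5' and 3' arm age correlations have opposite (nonzero) signs

Direction is ``to_5p`` when the fraction rises with age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, SampleMetadata
from .stats import spearman_with_p


@dataclass
class ArmShiftRecord:
    precursor_id: str
    sc_fraction: float
    p_fraction: float
    range_fraction: float
    sc_5p: float
    sc_3p: float
    direction: str  # to_5p | to_3p


def five_prime_fraction(expr5, expr3) -> np.ndarray:
    """Per-sample 5' share of total arm expression, on the linear scale.

    Entries where both arms are zero are nan (flagged missing).
    """
    e5 = np.asarray(expr5, dtype=float)
    e3 = np.asarray(expr3, dtype=float)
    if (e5 < 0).any() or (e3 < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = e5 + e3
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, e5 / np.where(total > 0, total, 1.0), np.nan)
    return frac


def detect_arm_shifts(
    arm_expr: ExpressionMatrix,
    pairs: pd.DataFrame,
    meta: SampleMetadata,
    sc_min: float = 0.2,
    p_max: float = 0.05,
    range_min: float = 0.2,
    log_base: float = 2.0,
    range_mode: str = "raw",
) -> list[ArmShiftRecord]:
    """Apply the four arm-shift criteria to every precursor pair.

    ``log_base`` de-logs the matrix before fractions are formed (None for
    already-linear values).  ``range_mode`` 'raw' uses per-sample extremes
    for criterion 3; 'age_mean' uses per-age mean fractions, which resists
    single-sample outliers.
    """
    meta = meta.aligned_to(arm_expr)
    ages = meta.ages.to_numpy(dtype=float)
    records = []
    for _, row in pairs.iterrows():
        pid, id5, id3 = row["precursor"], row["mirna_5p"], row["mirna_3p"]
        if id5 not in arm_expr.values.index or id3 not in arm_expr.values.index:
            warnings.warn(f"pair {pid}: arm missing from matrix, skipped")
            continue
        v5 = arm_expr.values.loc[id5].to_numpy(dtype=float)
        v3 = arm_expr.values.loc[id3].to_numpy(dtype=float)
        if log_base is not None:
            v5 = np.power(log_base, v5)
            v3 = np.power(log_base, v3)
        frac = five_prime_fraction(v5, v3)
        ok = np.isfinite(frac)
        if ok.sum() < 4:
            continue
        sc_f, p_f = spearman_with_p(frac[ok], ages[ok])
        if not np.isfinite(sc_f):
            continue
        if range_mode == "age_mean":
            means = pd.Series(frac[ok]).groupby(ages[ok]).mean()
            rng_f = float(means.max() - means.min())
        else:
            rng_f = float(np.nanmax(frac) - np.nanmin(frac))
        sc5, _ = spearman_with_p(v5[ok], ages[ok])
        sc3, _ = spearman_with_p(v3[ok], ages[ok])
        crit = (
            abs(sc_f) > sc_min
            and p_f <= p_max
            and rng_f > range_min
            and np.isfinite(sc5) and np.isfinite(sc3)
            and sc5 != 0 and sc3 != 0
            and np.sign(sc5) != np.sign(sc3)
        )
        if crit:
            records.append(ArmShiftRecord(
                precursor_id=pid, sc_fraction=float(sc_f), p_fraction=float(p_f),
                range_fraction=rng_f, sc_5p=float(sc5), sc_3p=float(sc3),
                direction="to_5p" if sc_f > 0 else "to_3p"))
    return records


def summarize(records: list[ArmShiftRecord]) -> dict:
    """Counts of shifts toward the 5' and the 3' mature form."""
    to5 = sum(1 for r in records if r.direction == "to_5p")
    return {"n_shifts": len(records), "to_5p": to5, "to_3p": len(records) - to5}
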