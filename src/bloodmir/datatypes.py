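"""Core domain containers for the blood miRNA aging pipeline.

All tabular data is carried in pandas objects wrapped by light dataclasses
that enforce the invariants downstream stages rely on (unique identifiers,
finite values, closed vocabularies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

#: closed vocabulary of disease groups: healthy controls, Parkinson's disease,
#: heart diseases, non-tumor lung diseases, lung cancer, other diseases.
GROUPS = ("HC", "PD", "HD", "NTLD", "LC", "OD")

SEXES = ("male", "female")


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of log-scale normalized intensities.

    ``values`` is a DataFrame indexed by feature id with sample ids as
    columns.  Duplicated ids and non-finite entries are rejected: every
    downstream stage assumes a dense, validated matrix.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature id(s): {dup[:5]}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample id(s): {dup[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float)).all():
            bad = np.argwhere(~np.isfinite(arr.astype(float)))[0]
            raise ValidationError(
                f"non-finite value at feature {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)])

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids), :])


@dataclass
class SampleMetadata:
    """Per-sample age (integer years), sex and disease group.

    ``table`` is indexed by sample id with columns ``age``, ``sex``,
    ``group``.
    """

    table: pd.DataFrame
    age_range: tuple[int, int] = (30, 79)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample id(s): {dup[:5]}")
        missing = {"age", "sex", "group"} - set(self.table.columns)
        if missing:
            raise ValidationError(f"metadata missing column(s): {sorted(missing)}")
        ages = self.table["age"]
        lo, hi = self.age_range
        if ((ages < lo) | (ages > hi)).any():
            bad = self.table.index[(ages < lo) | (ages > hi)][0]
            raise ValidationError(f"age outside [{lo}, {hi}] for sample {bad!r}")
        bad_sex = set(self.table["sex"]) - set(SEXES)
        if bad_sex:
            raise ValidationError(f"unknown sex value(s): {sorted(bad_sex)}")
        bad_grp = set(self.table["group"]) - set(GROUPS)
        if bad_grp:
            raise ValidationError(f"unknown group value(s): {sorted(bad_grp)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def ages(self) -> pd.Series:
        return self.table["age"]

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def aligned_to(self, expr: ExpressionMatrix) -> "SampleMetadata":
        """Metadata reindexed to the matrix's sample order (must cover it)."""
        missing = set(expr.sample_ids) - set(self.table.index)
        if missing:
            raise ValidationError(f"metadata missing sample(s): {sorted(missing)[:5]}")
        return SampleMetadata(self.table.loc[expr.sample_ids], self.age_range)


EVIDENCE_LEVELS = ("strong", "weak", "predicted")


@dataclass
class InteractionTable:
    """miRNA -> gene interactions with an evidence level per row.

    ``table`` has columns ``mirna_id``, ``gene_id``, ``evidence``; duplicate
    (mirna, gene, evidence) triples are rejected.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"mirna_id", "gene_id", "evidence"} - set(self.table.columns)
        if missing:
            raise ValidationError(f"interaction table missing column(s): {sorted(missing)}")
        bad = set(self.table["evidence"]) - set(EVIDENCE_LEVELS)
        if bad:
            raise ValidationError(f"unknown evidence level(s): {sorted(bad)}")
        if self.table.duplicated(["mirna_id", "gene_id", "evidence"]).any():
            row = self.table[self.table.duplicated(["mirna_id", "gene_id", "evidence"])].iloc[0]
            raise ValidationError(
                f"duplicate interaction: {row['mirna_id']} -> {row['gene_id']} ({row['evidence']})"
            )

    def strong(self) -> pd.DataFrame:
        return self.table[self.table["evidence"] == "strong"]


@dataclass
class AgeAssociationRecord:
    """Per-miRNA association summary: Spearman/Pearson/distance correlation
    with age, Wilcoxon sex test, correlation-cluster id and nonlinearity flag.

    ``None`` p-values flag tests that were undefined (constant expression,
    single-sex cohort)."""

    feature_id: str
    sc: float | None = None
    sc_p: float | None = None
    sc_p_adj: float | None = None
    pc: float | None = None
    dc: float | None = None
    sex_p: float | None = None
    sex_p_adj: float | None = None
    cluster: int | None = None
    nonlinear: str = "none"  # none | increasing | decreasing


def records_to_frame(records: list[AgeAssociationRecord]) -> pd.DataFrame:
    """Tabular view of association records, indexed by feature id."""
    rows = [vars(r).copy() for r in records]
    df = pd.DataFrame(rows).set_index("feature_id")
    return df
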