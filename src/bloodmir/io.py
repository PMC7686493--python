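"""Readers and writers for the pipeline's tabular formats.

All tables are tab-separated, UTF-8, '.' decimal.  Matrices have a header
row of sample ids and feature ids in the first column.  Category
collections use the GMT dialect (name, description, members).  Result
records are serialized as JSON with sorted keys so reruns are
byte-comparable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    InteractionTable,
    SampleMetadata,
    ValidationError,
)

_FLOAT_FMT = "%.10g"


def read_matrix(path) -> ExpressionMatrix:
    """Read a features x samples TSV matrix (header = sample ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"cannot parse matrix {path}: {exc}") from exc
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValidationError(
                f"non-numeric cell at feature {row!r}, sample {col!r} in {path}"
            )
        values[col] = converted
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    values.index.name = "feature_id"
    return ExpressionMatrix(values)


def write_matrix(expr: ExpressionMatrix, path) -> None:
    df = expr.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_metadata(path, age_range=(30, 79)) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df["age"] = df["age"].astype(int)
    return SampleMetadata(df[["age", "sex", "group"]], tuple(age_range))


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_interactions(path) -> InteractionTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return InteractionTable(df[["mirna_id", "gene_id", "evidence"]])


def write_interactions(tab: InteractionTable, path) -> None:
    tab.table.to_csv(path, sep="\t", index=False)


def read_pair_table(path) -> pd.DataFrame:
    """Arm-pair table: precursor, mirna_5p, mirna_3p."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"precursor", "mirna_5p", "mirna_3p"} - set(df.columns)
    if missing:
        raise ValidationError(f"pair table missing column(s): {sorted(missing)}")
    return df


def write_pair_table(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_presence(path) -> pd.DataFrame:
    """miRNA x compound boolean presence matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.astype(int).astype(bool)


def write_presence(presence: pd.DataFrame, path) -> None:
    presence.astype(int).to_csv(path, sep="\t")


def read_gmt(path) -> dict[str, set[str]]:
    """GMT category collection: name <tab> description <tab> members..."""
    categories: dict[str, set[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        name = fields[0]
        if name in categories:
            raise ValidationError(f"duplicate GMT category: {name!r}")
        categories[name] = set(fields[2:])
    return categories


def write_gmt(categories: dict[str, set[str]], path) -> None:
    lines = []
    for name in categories:
        members = sorted(categories[name])
        lines.append("\t".join([name, "na"] + members))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path, schema_version: str = "1") -> None:
    """Deterministic JSON artifact (sorted keys, no timestamps)."""
    payload = {"schema_version": schema_version, **obj} if isinstance(obj, dict) else obj
    text = json.dumps(payload, sort_keys=True, indent=1, default=_json_default,
                      allow_nan=True)
    Path(path).write_text(text + "\n", encoding="utf-8")


def read_json(path):
    return json.loads(Path(path).read_text(encoding="utf-8"))
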