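"""Tabular IO contracts.

All tables are TSV, UTF-8, '.' decimal, with missing values serialised
as ``NA``.  Readers validate headers and key uniqueness and report
row-level errors; writers are the exact inverse so that a write/read
round-trip is the identity.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "TableValidationError",
    "read_table",
    "read_samples",
    "read_scalars",
    "read_profiles",
    "read_genes",
    "read_gene_annotation",
    "write_table",
    "write_tables",
]

NA_REP = "NA"

_SCHEMAS: dict[str, dict[str, str]] = {
    "samples": {
        "sample_id": "str",
        "subject_id": "str",
        "arm": "str",
        "nominal_day": "int",
        "collection_time": "float",
    },
    "scalars": {"sample_id": "str", "variable": "str", "value": "float"},
    "profiles": {
        "sample_id": "str",
        "layer": "str",
        "feature_id": "str",
        "count": "float",
    },
    "genes": {"sample_id": "str", "gene_id": "str", "count": "float"},
    "gene_annotation": {"gene_id": "str", "family": "str"},
    "metrics": {"sample_id": "str", "variable": "str", "value": "float"},
}

#: Key columns that must be unique per table.
_KEYS: dict[str, list[str]] = {
    "samples": ["subject_id", "nominal_day"],
    "scalars": ["sample_id", "variable"],
    "profiles": ["sample_id", "layer", "feature_id"],
    "genes": ["sample_id", "gene_id"],
    "gene_annotation": ["gene_id"],
}


class TableValidationError(ValueError):
    """A table violates its contract (header, types or key uniqueness)."""


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate one of the pipeline's TSV tables."""
    schema = _SCHEMAS.get(kind)
    if schema is None:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    if not path.exists():
        raise TableValidationError(f"{path}: file not found")
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_REP], keep_default_na=False)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path}: missing columns {missing}")
    for col, typ in schema.items():
        if typ in ("int", "float"):
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                row = int(bad.idxmax()) + 2  # 1-based, counting the header
                raise TableValidationError(
                    f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                    f"in column {col!r} at line {row}"
                )
            if typ == "int":
                if converted.dropna().mod(1).ne(0).any():
                    raise TableValidationError(f"{path}: non-integer value in {col!r}")
                df[col] = converted.astype("Int64").astype("int64")
            else:
                df[col] = converted
    keys = _KEYS.get(kind)
    if keys:
        dup = df.duplicated(subset=keys)
        if dup.any():
            row = int(dup.idxmax()) + 2
            key = tuple(df.loc[dup.idxmax(), keys])
            raise TableValidationError(f"{path}: duplicate key {key} at line {row}")
    return df


def read_samples(path):
    return read_table(path, "samples")


def read_scalars(path):
    return read_table(path, "scalars")


def read_profiles(path):
    return read_table(path, "profiles")


def read_genes(path):
    return read_table(path, "genes")


def read_gene_annotation(path):
    return read_table(path, "gene_annotation")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=NA_REP)


def write_tables(frames: dict[str, pd.DataFrame], outdir: str | Path) -> dict[str, Path]:
    """Write a dict of frames as ``<name>.tsv`` files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in frames.items():
        p = outdir / f"{name}.tsv"
        write_table(df, p)
        paths[name] = p
    return paths
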