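"""Tabular I/O for the pipeline: expression matrices, sample metadata,
gene-ID maps and GMT gene-set collections.

Expression matrices are plain :class:`pandas.DataFrame` objects with genes
in the rows and samples in the columns, on linear (intensity / TPM-like)
scale. Metadata is a DataFrame indexed by sample id. Delimiters are chosen
from the file extension (``.tsv``/``.txt`` -> tab, ``.csv`` -> comma); no
content sniffing is performed.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "collapse_gene_ids",
    "read_gene_map",
    "read_metadata",
    "write_metadata",
    "read_gmt",
    "write_gmt",
    "METADATA_COLUMNS",
]

#: Required columns of a sample-metadata table.
METADATA_COLUMNS = (
    "compound",
    "dose_group",
    "time_h",
    "replicate",
    "is_control",
    "control_group_key",
)


def _sep_for(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return ","
    return "\t"


def _check_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    try:
        values = df.astype(float)
    except (TypeError, ValueError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"{path}: non-numeric value at row {row!r}, column {col!r}"
                ) from None
        raise
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError(f"{path}: expression values must be finite")
    return values


def read_expression(
    path: str | Path, orientation: str = "genes_in_rows"
) -> pd.DataFrame:
    """Read an expression table into a genes x samples DataFrame.

    Parameters
    ----------
    path:
        TSV/CSV file with a header row and identifiers in the first column.
    orientation:
        ``"genes_in_rows"`` (default) or ``"samples_in_rows"``; the returned
        frame is always genes x samples.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path)
    with open(path, newline="") as handle:
        header = next(csv.reader(handle, delimiter=sep), None)
    if header is None:
        raise ValueError(f"{path}: empty file")
    labels = header[1:]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"{path}: duplicated column labels {dupes}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = _check_numeric(df, path)
    if orientation == "samples_in_rows":
        df = df.T
    if df.columns.duplicated().any() or df.columns.isna().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples DataFrame; round-trips exactly with
    :func:`read_expression`."""
    expr.to_csv(path, sep=_sep_for(path))


def collapse_gene_ids(
    expr: pd.DataFrame, mapping: Mapping[str, str]
) -> pd.DataFrame:
    """Map row identifiers to gene symbols and collapse duplicates.

    Rows whose identifier is absent from ``mapping`` are dropped. When
    several source rows map onto one symbol, each sample's value is the
    per-sample median over those rows (missing values dropped before the
    median). Idempotent on an already-collapsed matrix.
    """
    for src, dst in mapping.items():
        if dst is None or str(dst) == "":
            raise ValueError(f"gene map has empty symbol for source {src!r}")
    keep = expr.index[expr.index.isin(mapping.keys())]
    if len(keep) == 0:
        raise ValueError("no gene identifier mapped; empty output")
    sub = expr.loc[keep]
    symbols = sub.index.map(lambda g: mapping[g])
    out = sub.groupby(symbols, sort=True).median()
    out.index.name = expr.index.name
    return out


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Read a two-column source-id -> gene-symbol table (no header)."""
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: gene map needs two columns")
    df = df.dropna(subset=[1])
    return dict(zip(df[0], df[1]))


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata table indexed by ``sample_id``.

    Required columns: compound, dose_group, time_h, replicate, is_control,
    control_group_key. Optional: ``alt`` and any further numeric analyte
    columns (hematology). Validates that every treated sample's control
    group contains at least one control sample.
    """
    meta = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    meta.index = meta.index.astype(str)
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata lacks columns {missing}")
    if meta.index.duplicated().any():
        dupes = sorted(meta.index[meta.index.duplicated()].unique())
        raise ValueError(f"duplicate sample ids {dupes}")
    meta = meta.copy()
    meta["is_control"] = meta["is_control"].astype(bool)
    meta["time_h"] = meta["time_h"].astype(float)
    if (meta["time_h"] < 0).any():
        raise ValueError("time_h must be non-negative")
    control_keys = set(meta.loc[meta["is_control"], "control_group_key"])
    orphans = meta.loc[
        ~meta["is_control"] & ~meta["control_group_key"].isin(control_keys)
    ]
    if len(orphans):
        raise ValueError(
            "treated samples without matched controls: "
            f"{sorted(orphans.index)[:5]}"
        )
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: ``name<TAB>description<TAB>gene1<TAB>...``.

    Duplicate genes within a set are dropped (first occurrence kept).
    """
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        lines = [line.rstrip("\n") for line in handle if line.strip()]
    if not lines:
        raise ValueError(f"{path}: empty GMT file")
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}: duplicate set name {name!r}")
        genes = list(dict.fromkeys(g for g in fields[2:] if g))
        sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, genes in sets.items():
            handle.write("\t".join([name, "na", *genes]) + "\n")
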