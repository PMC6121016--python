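"""Tab-separated I/O helpers.

All tabular interchange is TSV: expression matrices have a header row of
sample ids and gene ids in the first column; purity tables map sample id to
purity; results tables carry one row per gene at full floating precision.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_purity_tsv",
    "read_groups_tsv",
    "write_results_tsv",
]


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes x samples TSV (gene ids in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    if df.isna().any().any():
        raise ValueError(f"missing values are not permitted in {path}")
    return df.astype(float)


def write_expression_tsv(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t")


def read_purity_tsv(path) -> pd.Series:
    """Read sample -> purity. Uses the 'reported_purity' column if present,
    otherwise the first numeric column after the sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    col = "reported_purity" if "reported_purity" in df.columns else df.columns[0]
    s = df[col].astype(float)
    s.name = "purity"
    return s


def read_groups_tsv(path) -> pd.Series:
    """Read sample -> group label ('normal'/'tumor')."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0].astype(str)
    s.name = "group"
    return s


def write_results_tsv(table: pd.DataFrame, path) -> None:
    """Write a per-gene results table at full (repr round-trip) precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", float_format="%.17g")
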