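"""Expression preprocessing: log2 transform and quantile normalization.

Abundance estimates such as RSEM or FPKM are non-negative and heavily
right-skewed. The model downstream assumes approximately Gaussian per-gene
expression, so raw values are log2-transformed with a data-driven offset
(the smallest strictly positive value in the matrix, which keeps zeros
finite without a magic pseudocount) and then quantile-normalized so every
sample shares one empirical distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["NormalizedExpression", "log2_transform", "quantile_normalize"]


@dataclass
class NormalizedExpression:
    """A genes x samples expression matrix plus a record of transforms applied.

    ``values`` is indexed by gene id with sample ids as columns.
    ``provenance`` is a list of dicts, one per transform step.
    """

    values: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, NormalizedExpression):
        return matrix.values
    return matrix


def _validate_raw(values: pd.DataFrame) -> None:
    if values.index.has_duplicates:
        raise ValueError("gene ids must be unique")
    if values.columns.has_duplicates:
        raise ValueError("sample ids must be unique")
    arr = values.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("expression matrix contains non-finite values")
    if (arr < 0).any():
        raise ValueError("raw expression values must be non-negative")


def log2_transform(raw: pd.DataFrame) -> NormalizedExpression:
    """log2(v + min_nonzero) with the offset taken over the whole matrix.

    Parameters
    ----------
    raw
        Genes x samples matrix of non-negative abundance values.

    Returns
    -------
    NormalizedExpression with the offset recorded in provenance.

    Raises
    ------
    ValueError
        If the matrix is all zeros (no offset can be computed) or contains
        negative / non-finite values.
    """
    raw = _as_frame(raw)
    _validate_raw(raw)
    arr = raw.to_numpy(dtype=float)
    positive = arr[arr > 0]
    if positive.size == 0:
        raise ValueError("all-zero expression matrix: no non-zero offset exists")
    offset = float(positive.min())
    out = pd.DataFrame(np.log2(arr + offset), index=raw.index, columns=raw.columns)
    return NormalizedExpression(
        values=out, provenance=[{"step": "log2", "offset": offset}]
    )


def _quantile_normalize_block(block: np.ndarray, frame: pd.DataFrame) -> np.ndarray:
    """Map each column of a scope unit onto the mean-of-sorted reference."""
    n_genes, n_samples = block.shape
    reference = np.sort(block, axis=0).mean(axis=1)
    out = np.empty_like(block)
    for j in range(n_samples):
        col = block[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_genes)
        assigned[order] = reference
        # ties take the mean of the reference values they span
        s = pd.Series(assigned)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return out


def quantile_normalize(
    matrix,
    scope: str = "joint",
    groups: pd.Series | None = None,
) -> NormalizedExpression:
    """Quantile-normalize sample columns so they share one distribution.

    Within each scope unit (all samples for ``scope='joint'``, each group of
    ``groups`` for ``scope='per_group'``) every column is replaced by the
    across-column mean of sorted values, assigned by within-column rank;
    tied values receive the mean of the reference values they span.

    Raises
    ------
    ValueError
        If a scope unit has fewer than two samples, or per_group is
        requested without group labels.
    """
    if scope not in ("joint", "per_group"):
        raise ValueError(f"unknown scope {scope!r}; use 'joint' or 'per_group'")
    provenance = list(matrix.provenance) if isinstance(matrix, NormalizedExpression) else []
    frame = _as_frame(matrix)
    arr = frame.to_numpy(dtype=float)
    out = np.empty_like(arr)

    if scope == "joint":
        units = {"all": np.arange(frame.shape[1])}
    else:
        if groups is None:
            raise ValueError("per_group normalization requires group labels")
        groups = groups.reindex(frame.columns)
        if groups.isna().any():
            missing = list(frame.columns[groups.isna()])
            raise ValueError(f"samples missing a group label: {missing}")
        units = {
            str(g): np.flatnonzero((groups == g).to_numpy())
            for g in pd.unique(groups)
        }

    for name, idx in units.items():
        if idx.size < 2:
            raise ValueError(
                f"quantile normalization needs >=2 samples per scope unit; "
                f"unit {name!r} has {idx.size}"
            )
        out[:, idx] = _quantile_normalize_block(arr[:, idx], frame)

    provenance.append({"step": "quantile_normalize", "scope": scope})
    return NormalizedExpression(
        values=pd.DataFrame(out, index=frame.index, columns=frame.columns),
        provenance=provenance,
    )
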