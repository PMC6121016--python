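"""Purity-confounding diagnostics.

When a gene is truly differential, its observed tumor expression
Y' = X + lambda * delta depends on the sample purity lambda, so its
expression correlates with purity across tumor samples; a null gene does
not. These diagnostics quantify that: per-gene Spearman correlation with
purity (with an optional purity-permutation null), decile grouping of the
correlations by a test statistic, and top-n average-|rho| curves over a
significance ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PurityCorrelationReport",
    "purity_correlation",
    "group_by_statistic",
    "top_n_correlation_curve",
]


@dataclass
class PurityCorrelationReport:
    """Per-gene Spearman rho between expression and tumor purity."""

    rho: pd.Series
    degenerate: pd.Series  # True where the expression row was constant
    rho_shuffled: pd.Series | None = None
    shuffle_seed: int | None = None
    deciles: pd.DataFrame | None = field(default=None)


def _spearman_rows(expr: np.ndarray, purity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman rho with average-rank ties; constant rows -> (0, flag)."""
    ranks_expr = pd.DataFrame(expr).rank(axis=1, method="average").to_numpy()
    ranks_pur = pd.Series(purity).rank(method="average").to_numpy()
    re_c = ranks_expr - ranks_expr.mean(axis=1, keepdims=True)
    rp_c = ranks_pur - ranks_pur.mean()
    denom = np.sqrt((re_c**2).sum(axis=1) * (rp_c**2).sum())
    degenerate = denom == 0
    rho = np.zeros(expr.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        rho[~degenerate] = (re_c[~degenerate] @ rp_c) / denom[~degenerate]
    return rho, degenerate


def purity_correlation(
    expr_tumor: pd.DataFrame,
    purities: pd.Series,
    shuffle: bool = False,
    seed: int | None = None,
) -> PurityCorrelationReport:
    """Spearman correlation of each gene's tumor expression with purity.

    Parameters
    ----------
    expr_tumor
        Genes x tumor-samples expression.
    purities
        Purity per tumor sample (aligned by sample id).
    shuffle
        Additionally compute rho against a single seed-controlled
        permutation of the purities — the empirical null.

    Constant expression rows get rho = 0 and a degenerate flag rather than
    being dropped.
    """
    if expr_tumor.shape[1] < 3:
        raise ValueError("need at least 3 tumor samples to correlate")
    purities = purities.reindex(expr_tumor.columns)
    if purities.isna().any():
        missing = list(expr_tumor.columns[purities.isna()])
        raise ValueError(f"tumor samples missing a purity value: {missing}")
    expr = expr_tumor.to_numpy(dtype=float)
    lam = purities.to_numpy(dtype=float)
    rho, degenerate = _spearman_rows(expr, lam)
    report = PurityCorrelationReport(
        rho=pd.Series(rho, index=expr_tumor.index, name="rho"),
        degenerate=pd.Series(degenerate, index=expr_tumor.index, name="degenerate"),
    )
    if shuffle:
        rng = np.random.default_rng(seed)
        rho_sh, _ = _spearman_rows(expr, rng.permutation(lam))
        report.rho_shuffled = pd.Series(
            rho_sh, index=expr_tumor.index, name="rho_shuffled"
        )
        report.shuffle_seed = seed
    return report


def group_by_statistic(
    rhos: pd.Series, statistics: pd.Series, n_groups: int = 10
) -> pd.DataFrame:
    """Bin genes into equal-size groups by statistic rank; summarize rho per bin.

    Genes are sorted by the statistic (ties broken by gene id for
    determinism) and split into ``n_groups`` contiguous bins of equal size
    (+/- 1). Returns a frame with one row per gene: its bin index (0 = lowest
    statistics) plus per-bin mean rho and mean |rho| broadcast to members.
    """
    if len(rhos) != len(statistics) or not rhos.index.equals(statistics.index):
        raise ValueError("rho and statistic vectors must be aligned")
    if len(rhos) < n_groups:
        raise ValueError(f"need at least {n_groups} genes for {n_groups} groups")
    order = (
        pd.DataFrame({"statistic": statistics})
        .reset_index()
        .sort_values(["statistic", rhos.index.name or "index"], kind="stable")
    )
    bins = np.array_split(np.arange(len(order)), n_groups)
    decile = np.empty(len(order), dtype=int)
    for g, idx in enumerate(bins):
        decile[idx] = g
    out = pd.DataFrame(
        {"statistic": order["statistic"].to_numpy(), "decile": decile},
        index=pd.Index(order.iloc[:, 0], name=rhos.index.name or "gene_id"),
    ).reindex(rhos.index)
    out["rho"] = rhos
    grp = out.groupby("decile")["rho"]
    out["decile_mean_rho"] = out["decile"].map(grp.mean())
    out["decile_mean_abs_rho"] = out["decile"].map(grp.apply(lambda s: s.abs().mean()))
    return out


def top_n_correlation_curve(
    rhos: pd.Series, fdr_ranks: pd.Series, n_grid
) -> pd.Series:
    """Mean |rho| over the top-n ranked genes, for each n in ``n_grid``.

    ``fdr_ranks`` gives each gene's position in the significance ranking
    (1 = most significant). Values of n beyond the gene count are truncated
    with a warning.
    """
    if not rhos.index.equals(fdr_ranks.index):
        raise ValueError("rho and rank vectors must be aligned")
    n_grid = np.asarray(n_grid, dtype=int)
    if np.any(n_grid < 1):
        raise ValueError("n values must be >= 1")
    total = len(rhos)
    if np.any(n_grid > total):
        warnings.warn(
            f"n values above the gene count ({total}) are truncated",
            RuntimeWarning,
            stacklevel=2,
        )
        n_grid = np.minimum(n_grid, total)
    abs_rho_by_rank = rhos.abs().to_numpy()[np.argsort(fdr_ranks.to_numpy(), kind="stable")]
    running_mean = np.cumsum(abs_rho_by_rank) / np.arange(1, total + 1)
    return pd.Series(running_mean[n_grid - 1], index=pd.Index(n_grid, name="n"))
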