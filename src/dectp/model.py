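"""The DECtp core: purity-weighted linear model, Wald test, FDR.

For gene i the stacked expression vector Z_i (n0 normal samples first, then
n1 tumor samples) is modeled as Z_i = W beta_i + eps_i with

    W = [[1, 0], ..., [1, 0], [1, lambda_1], ..., [1, lambda_n1]],

so beta_i = (m_i, mu_i): the pure-normal mean and the pure-tumor effect.
The fit is ordinary least squares, beta_hat = (W'W)^{-1} W' Z. Residual
variances are estimated separately in the normal and tumor groups with
n - 2 denominators, optionally shrunk toward the cross-gene geometric mean,
and combined through the heteroscedastic sandwich

    var(beta_hat) = H1 Sigma H1' + H2 Sigma' H2',   H = (W'W)^{-1} W',

where H1/H2 are the normal/tumor column blocks of H and Sigma = sigma^2 I,
Sigma' = sigma'^2 I. H0: mu_i = 0 is tested with the Wald statistic
t_i = beta_hat[2] / sqrt(var(beta_hat)[2,2]) referred to a t distribution
with n0 + n1 - 2 degrees of freedom, followed by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignMatrix",
    "build_design_matrix",
    "fit_gene",
    "estimate_group_variances",
    "shrink_variances",
    "beta_covariance",
    "wald_test",
    "benjamini_hochberg",
    "run_dectp",
]

#: minimum samples per group, forced by the n - 2 variance denominators
MIN_GROUP_SIZE = 3


@dataclass(frozen=True)
class DesignMatrix:
    """Two-column design: intercept and the purity-weighted effect column."""

    W: np.ndarray
    n_normal: int
    n_tumor: int
    purities: np.ndarray

    @property
    def df(self) -> int:
        """Degrees of freedom of the Wald reference distribution."""
        return self.n_normal + self.n_tumor - 2

    def hat(self) -> np.ndarray:
        """H = (W'W)^{-1} W', the 2 x (n0+n1) projection onto coefficients."""
        W = self.W
        return np.linalg.solve(W.T @ W, W.T)


def build_design_matrix(n_normal: int, purities) -> DesignMatrix:
    """Build W for ``n_normal`` normal samples followed by one tumor row per purity.

    Purities must lie in (0, 1]; a nominal tumor sample with purity 0 carries
    no tumor signal and would make the effect column degenerate.
    """
    purities = np.asarray(purities, dtype=float)
    if n_normal < MIN_GROUP_SIZE or purities.size < MIN_GROUP_SIZE:
        raise ValueError(
            f"need at least {MIN_GROUP_SIZE} samples per group for the n-2 "
            f"variance denominators (got n_normal={n_normal}, "
            f"n_tumor={purities.size})"
        )
    if not np.all(np.isfinite(purities)):
        raise ValueError("purities must be finite")
    if np.any(purities <= 0) or np.any(purities > 1):
        bad = purities[(purities <= 0) | (purities > 1)]
        raise ValueError(f"purities must lie in (0, 1]; offending values: {bad}")
    n_tumor = purities.size
    W = np.ones((n_normal + n_tumor, 2))
    W[:n_normal, 1] = 0.0
    W[n_normal:, 1] = purities
    return DesignMatrix(W=W, n_normal=n_normal, n_tumor=n_tumor, purities=purities)


def fit_gene(z, design: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of one gene: beta_hat = (W'W)^{-1} W' z.

    Returns ``(beta, residuals)`` with beta = (normal mean, tumor effect).
    """
    z = np.asarray(z, dtype=float)
    if z.shape != (design.n_normal + design.n_tumor,):
        raise ValueError(
            f"expression vector has length {z.size}, design expects "
            f"{design.n_normal + design.n_tumor}"
        )
    if not np.all(np.isfinite(z)):
        raise ValueError("expression vector contains non-finite values")
    W = design.W
    beta = np.linalg.solve(W.T @ W, W.T @ z)
    residuals = z - W @ beta
    return beta, residuals


def estimate_group_variances(
    residuals, n_normal: int, n_tumor: int
) -> tuple[float, float]:
    """Group-wise residual variances with n - 2 denominators.

    sigma^2 = sum of squared normal-group residuals / (n0 - 2) and
    sigma'^2 = sum of squared tumor-group residuals / (n1 - 2).
    """
    residuals = np.asarray(residuals, dtype=float)
    if n_normal - 2 <= 0 or n_tumor - 2 <= 0:
        raise ValueError("group sizes must exceed 2 for the n-2 denominators")
    if residuals.size != n_normal + n_tumor:
        raise ValueError("residual vector length does not match group sizes")
    s2_normal = float(np.sum(residuals[:n_normal] ** 2) / (n_normal - 2))
    s2_tumor = float(np.sum(residuals[n_normal:] ** 2) / (n_tumor - 2))
    return s2_normal, s2_tumor


def _floor_zeros(variances: np.ndarray) -> np.ndarray:
    """Floor exact-zero variances so the geometric mean is defined."""
    positive = variances[variances > 0]
    floor = float(np.percentile(positive, 1)) if positive.size else 1e-8
    return np.where(variances > 0, variances, floor)


def shrink_variances(variances, weight: float = 0.5) -> np.ndarray:
    """Shrink per-gene variances toward their cross-gene geometric mean.

    On the log scale: log s~^2 = (1 - w) log s^2 + w mean(log s^2). w = 0 is
    the identity; w = 1 maps every gene to the group geometric mean. Called
    once per sample group. Exact zeros are floored at the 1st percentile of
    the positive variances (1e-8 if none) before taking logs.
    """
    variances = np.asarray(variances, dtype=float)
    if not 0.0 <= weight <= 1.0:
        raise ValueError("shrinkage weight must lie in [0, 1]")
    if np.any(variances < 0):
        raise ValueError("variances must be non-negative")
    if weight == 0.0:
        return variances.copy()
    log_v = np.log(_floor_zeros(variances))
    shrunk = (1.0 - weight) * log_v + weight * log_v.mean()
    return np.exp(shrunk)


def beta_covariance(
    design: DesignMatrix, sigma2_normal: float, sigma2_tumor: float
) -> np.ndarray:
    """Heteroscedastic sandwich var(beta_hat) = H1 Sigma H1' + H2 Sigma' H2'."""
    if sigma2_normal < 0 or sigma2_tumor < 0:
        raise ValueError("variances must be non-negative")
    H = design.hat()
    H1 = H[:, : design.n_normal]
    H2 = H[:, design.n_normal :]
    return sigma2_normal * (H1 @ H1.T) + sigma2_tumor * (H2 @ H2.T)


def wald_test(beta, var_beta, df: int) -> tuple[float, float]:
    """Wald test of the tumor effect: t = beta[2] / sqrt(var[2,2]), t_{df} reference.

    A zero variance with a zero effect is the fully degenerate case (t = 0,
    p = 1); a zero variance with a nonzero effect yields p = 0 with a warning.
    """
    beta = np.asarray(beta, dtype=float)
    var_beta = np.asarray(var_beta, dtype=float)
    effect = beta[1]
    v = var_beta[1, 1]
    if v < 0:
        raise ValueError("effect variance must be non-negative")
    if v == 0.0:
        if effect == 0.0:
            return 0.0, 1.0
        warnings.warn(
            "zero effect variance with nonzero effect: p-value degenerates to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(np.sign(effect) * np.inf), 0.0
    t = float(effect / np.sqrt(v))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, p


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _align_inputs(expr, groups: pd.Series, purities: pd.Series):
    """Order samples normal-first / tumor-in-purity-order; validate coverage."""
    values = expr.values if hasattr(expr, "values") and hasattr(expr, "provenance") else expr
    if not isinstance(values, pd.DataFrame):
        raise TypeError("expression must be a DataFrame or NormalizedExpression")
    groups = groups.reindex(values.columns)
    if groups.isna().any():
        missing = list(values.columns[groups.isna()])
        raise ValueError(f"samples without a group label: {missing}")
    bad = set(groups.unique()) - {"normal", "tumor"}
    if bad:
        raise ValueError(f"group labels must be 'normal' or 'tumor'; got {sorted(bad)}")
    normal_ids = [s for s in values.columns if groups[s] == "normal"]
    tumor_ids = [s for s in values.columns if groups[s] == "tumor"]
    missing_purity = [s for s in tumor_ids if s not in purities.index]
    if missing_purity:
        raise ValueError(f"tumor samples missing a purity value: {missing_purity}")
    lam = purities.loc[tumor_ids].astype(float)
    return values, normal_ids, tumor_ids, lam


def run_dectp(
    expr,
    groups: pd.Series,
    purities: pd.Series,
    shrink_weight: float = 0.5,
) -> pd.DataFrame:
    """Run the full purity-corrected differential expression pipeline.

    Parameters
    ----------
    expr
        Genes x samples DataFrame (or NormalizedExpression) on the Gaussian
        (log) scale: normal columns hold X, tumor columns hold the observed
        mixture Y'.
    groups
        Per-sample labels in {'normal', 'tumor'}.
    purities
        Per-tumor-sample purity lambda in (0, 1].
    shrink_weight
        Weight of the geometric-mean variance shrinkage (0 disables it).

    Returns
    -------
    DataFrame indexed by gene id, in input gene order, with columns
    beta_normal_mean, beta_tumor_effect, sigma2_normal, sigma2_tumor,
    sigma2_normal_shrunk, sigma2_tumor_shrunk, wald_t, p_value, fdr, rank.
    Rank orders genes by fdr (ties broken by p-value, then gene id).

    Notes
    -----
    Two-pass execution: all genes are fitted first, the pooled per-group
    variance vectors are shrunk jointly, then each gene is tested.
    """
    values, normal_ids, tumor_ids, lam = _align_inputs(expr, groups, purities)
    design = build_design_matrix(len(normal_ids), lam.to_numpy())
    n0, n1 = design.n_normal, design.n_tumor

    Z = values[normal_ids + tumor_ids].to_numpy(dtype=float)  # genes x samples
    if not np.all(np.isfinite(Z)):
        raise ValueError("expression matrix contains non-finite values")
    H = design.hat()
    beta = Z @ H.T  # genes x 2
    resid = Z - beta @ design.W.T

    # snap numerically-zero quantities: a gene that is constant within both
    # groups has residuals and effect that are pure rounding noise, and the
    # ratio of two rounding errors is meaningless
    scale = np.maximum(np.abs(Z).max(axis=1), 1.0)
    tol = 1e3 * np.finfo(float).eps * scale
    beta[:, 1] = np.where(np.abs(beta[:, 1]) < tol, 0.0, beta[:, 1])

    s2_normal = (resid[:, :n0] ** 2).sum(axis=1) / (n0 - 2)
    s2_tumor = (resid[:, n0:] ** 2).sum(axis=1) / (n1 - 2)
    s2_normal = np.where(s2_normal < tol**2, 0.0, s2_normal)
    s2_tumor = np.where(s2_tumor < tol**2, 0.0, s2_tumor)
    s2_normal_sh = shrink_variances(s2_normal, shrink_weight)
    s2_tumor_sh = shrink_variances(s2_tumor, shrink_weight)

    H1, H2 = H[:, :n0], H[:, n0:]
    a = float((H1 @ H1.T)[1, 1])
    b = float((H2 @ H2.T)[1, 1])
    v22 = s2_normal_sh * a + s2_tumor_sh * b

    effect = beta[:, 1]
    t = np.zeros_like(effect)
    p = np.ones_like(effect)
    ok = v22 > 0
    t[ok] = effect[ok] / np.sqrt(v22[ok])
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), design.df)
    degenerate = ~ok & (effect != 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero effect variance but "
            "nonzero effect: p set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        t[degenerate] = np.sign(effect[degenerate]) * np.inf
        p[degenerate] = 0.0

    fdr = benjamini_hochberg(p)

    table = pd.DataFrame(
        {
            "beta_normal_mean": beta[:, 0],
            "beta_tumor_effect": effect,
            "sigma2_normal": s2_normal,
            "sigma2_tumor": s2_tumor,
            "sigma2_normal_shrunk": s2_normal_sh,
            "sigma2_tumor_shrunk": s2_tumor_sh,
            "wald_t": t,
            "p_value": p,
            "fdr": fdr,
        },
        index=pd.Index(values.index, name="gene_id"),
    )
    order = table.reset_index().sort_values(
        ["fdr", "p_value", "gene_id"], kind="stable"
    )
    rank = pd.Series(np.arange(1, len(table) + 1), index=order["gene_id"])
    table["rank"] = rank.reindex(table.index).astype(int)
    return table
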