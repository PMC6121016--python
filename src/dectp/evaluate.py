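"""Benchmarking against a two-sample t-test baseline via ROC/AUC.

Methods are scored per gene by the absolute value of their test statistic
(equivalent to 1 - p at a fixed reference distribution) and compared to
ground-truth DEG labels with the Mann-Whitney formulation of the AUC:
the probability that a randomly chosen true-DEG gene outranks a randomly
chosen non-DEG gene, ties counted 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from dectp.model import run_dectp
from dectp.simulate import SimulatedDataset

__all__ = ["MethodComparison", "two_sample_t_test", "roc_auc", "compare_methods"]


def two_sample_t_test(x, y) -> tuple[float, float]:
    """Pooled-variance two-sample t-test of tumor (y) minus normal (x).

    Returns ``(t, p)`` with df = n0 + n1 - 2; the zero-pooled-variance,
    equal-means degenerate case yields (0, 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(y, x, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero pooled variance
        if np.mean(y) == np.mean(x):
            return 0.0, 1.0
        return float(np.sign(np.mean(y) - np.mean(x)) * np.inf), 0.0
    return t, p


def _t_test_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise pooled t statistics (genes x samples inputs)."""
    res = stats.ttest_ind(y, x, axis=1, equal_var=True)
    t = np.asarray(res.statistic, dtype=float)
    # degenerate rows: zero pooled variance
    nan = np.isnan(t)
    if nan.any():
        diff = y[nan].mean(axis=1) - x[nan].mean(axis=1)
        t[nan] = np.where(diff == 0, 0.0, np.sign(diff) * np.inf)
    return t


def roc_auc(scores, truth_labels) -> float:
    """AUC as P(score of a random positive > score of a random negative).

    Raises ValueError if the truth contains a single class.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth_labels).astype(bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth labels must be aligned")
    if truth.all() or not truth.any():
        raise ValueError("ROC needs both DEG and non-DEG genes in the truth")
    # map +/- inf to finite extremes: only rank order matters for the AUC
    finite = scores[np.isfinite(scores)]
    hi = finite.max() + 1.0 if finite.size else 1.0
    lo = finite.min() - 1.0 if finite.size else -1.0
    scores = np.nan_to_num(scores, posinf=hi, neginf=lo)
    return float(roc_auc_score(truth.astype(int), scores))


@dataclass
class MethodComparison:
    """Aligned per-gene scores, truth labels and AUCs for each method."""

    scores: pd.DataFrame  # one column per method, indexed by gene
    truth: pd.Series
    aucs: dict[str, float]
    config: object = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": list(self.aucs),
                "auc": list(self.aucs.values()),
                "n_genes": len(self.truth),
                "n_true_deg": int(self.truth.sum()),
            }
        )


def compare_methods(
    dataset: SimulatedDataset,
    shrink_weight: float = 0.5,
    use_reported_purities: bool = True,
) -> MethodComparison:
    """Score the purity-corrected caller and the t-test on one dataset.

    Both methods see the observed data only: pure-normal columns X and
    mixed-tumor columns Y'. The caller additionally receives the (possibly
    noisy) reported purities. Genes are ranked by |statistic|.
    """
    purities = (
        dataset.reported_purities if use_reported_purities else dataset.true_purities
    )
    table = run_dectp(
        dataset.expression, dataset.groups, purities, shrink_weight=shrink_weight
    )
    x = dataset.pure_normal.to_numpy(dtype=float)
    y = dataset.mixed_tumor.to_numpy(dtype=float)
    t_baseline = _t_test_matrix(x, y)

    scores = pd.DataFrame(
        {
            "dectp": np.abs(table["wald_t"].to_numpy()),
            "t_test": np.abs(t_baseline),
        },
        index=dataset.truth.index,
    )
    aucs = {
        method: roc_auc(scores[method].to_numpy(), dataset.truth.to_numpy())
        for method in scores.columns
    }
    return MethodComparison(
        scores=scores, truth=dataset.truth, aucs=aucs, config=dataset.config
    )
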