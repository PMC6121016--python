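import numpy as np
import pandas as pd
import pytest

from dectp.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def worked_example():
    """Three normal samples (0,1,2) and three pure tumors (3,4,5): the
    hand-derivable case with all purities 1, where the Wald statistic is
    (ybar - xbar)/sqrt(s2n/n0 + s2t/n1) = 3/sqrt(4/3)."""
    z = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
    return {"z": z, "n_normal": 3, "purities": np.ones(3), "t": 3 / np.sqrt(4 / 3)}


@pytest.fixture(scope="session")
def small_dataset():
    """A small purity-confounded dataset with both DEG classes present."""
    return simulate_dataset(
        SimulationConfig(seed=42, n_genes=200, n_normal=10, n_tumor=10)
    )


def brute_force_normal_equations(z, W):
    """Independent 2x2 least-squares oracle via Cramer's rule on scalar sums."""
    w = W[:, 1]
    n = len(z)
    a11, a12, a22 = float(n), float(w.sum()), float((w**2).sum())
    b1, b2 = float(z.sum()), float((w * z).sum())
    det = a11 * a22 - a12 * a12
    beta1 = (b1 * a22 - a12 * b2) / det
    beta2 = (a11 * b2 - a12 * b1) / det
    return np.array([beta1, beta2])


def brute_force_bh(p):
    """Step-up BH oracle: sort, scale by m/k, enforce monotonicity, cap at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def brute_force_auc(scores, labels):
    """Exhaustive pair enumeration with half credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))
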