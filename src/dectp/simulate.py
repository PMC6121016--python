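"""Purity-confounded expression simulation with known DEG truth.

The generative model mirrors the mixture assumption the caller is built on.
For gene i, pure-normal expression is X_ij ~ N(m_i, sigma_i^2); the pure
tumor signal is Y_ij = X_ij + delta_ij with delta_ij ~ N(mu_i, tau_i^2), so
marginally Y_ij ~ N(m_i', sigma_i'^2) with m_i' = m_i + mu_i and
sigma_i'^2 = sigma_i^2 + tau_i^2. Observed tumor expression mixes both
through the per-sample purity lambda_j ~ Uniform(purity_range):

    Y'_ij = lambda_j Y_ij + (1 - lambda_j) X_ij.

Gene i is a true DEG iff |m_i - m_i'| >= delta (inclusive). Reported
purities may carry Gaussian estimation noise (clipped back into the purity
range), emulating imperfect purity estimates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GeneParams",
    "SimulatedDataset",
    "sample_gene_params",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the simulation; ``seed`` is mandatory for reproducibility.

    Defaults emulate a bulk tumor/normal log-expression study: base means
    near 8 log2 units with spread 2, per-gene standard deviations of a few
    tenths to ~1, ~60% of genes carrying a N(0, 2^2) pure-tumor effect (the
    rest exactly null), and purities uniform on [0.05, 0.95]. With the
    default effect mixture, thresholds delta = 1, 2, 3 label roughly
    37%/19%/8% of genes as true DEGs.
    """

    seed: int
    n_genes: int = 2000
    n_normal: int = 50
    n_tumor: int = 50
    delta_threshold: float = 2.0
    purity_range: tuple[float, float] = (0.05, 0.95)
    purity_noise_sd: float = 0.0
    # effect distribution: 'mixture' (point mass at 0 w.p. 1-deg_fraction,
    # else N(0, effect_sd^2)), 'fixed' (all mu = effect_value), or 'none'
    effect_kind: str = "mixture"
    deg_fraction: float = 0.6
    effect_sd: float = 2.0
    effect_value: float = 0.0
    base_mean_loc: float = 8.0
    base_mean_scale: float = 2.0
    sigma_offset: float = 0.25  # sd floor: sigma_i = |N(0,1)| + sigma_offset
    sigma2_fixed: float | None = None
    tau2_fixed: float | None = None

    def __post_init__(self):
        if min(self.n_genes, self.n_normal, self.n_tumor) < 3:
            raise ValueError("n_genes, n_normal and n_tumor must all be >= 3")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi < 1.0 or (0.0 < lo <= hi <= 1.0)):
            raise ValueError("purity bounds must satisfy 0 < low <= high <= 1")
        if self.effect_kind not in ("mixture", "fixed", "none"):
            raise ValueError("effect_kind must be 'mixture', 'fixed' or 'none'")
        if not 0.0 <= self.deg_fraction <= 1.0:
            raise ValueError("deg_fraction must lie in [0, 1]")
        if self.purity_noise_sd < 0:
            raise ValueError("purity_noise_sd must be >= 0")


@dataclass(frozen=True)
class GeneParams:
    """Per-gene generative parameters (arrays over genes)."""

    m: np.ndarray  # pure-normal mean
    sigma2: np.ndarray  # pure-normal variance
    mu: np.ndarray  # pure-tumor mean shift
    tau2: np.ndarray  # variance of the per-sample tumor shift

    @property
    def m_prime(self) -> np.ndarray:
        """Pure-tumor mean m' = m + mu."""
        return self.m + self.mu

    @property
    def sigma2_prime(self) -> np.ndarray:
        """Pure-tumor variance sigma'^2 = sigma^2 + tau^2."""
        return self.sigma2 + self.tau2


@dataclass
class SimulatedDataset:
    pure_normal: pd.DataFrame  # genes x normal samples (X, the observed normal group)
    pure_tumor: pd.DataFrame  # genes x tumor samples (Y, unobservable in reality)
    normal_component: pd.DataFrame  # genes x tumor samples: each tumor sample's own admixed-normal signal
    mixed_tumor: pd.DataFrame  # genes x tumor samples (Y', the observed data)
    true_purities: pd.Series
    reported_purities: pd.Series
    truth: pd.Series  # bool per gene: |m - m'| >= delta
    params: GeneParams
    config: SimulationConfig

    @property
    def expression(self) -> pd.DataFrame:
        """Observed matrix: pure-normal plus mixed-tumor columns."""
        return pd.concat([self.pure_normal, self.mixed_tumor], axis=1)

    @property
    def groups(self) -> pd.Series:
        labels = ["normal"] * self.pure_normal.shape[1] + [
            "tumor"
        ] * self.mixed_tumor.shape[1]
        return pd.Series(labels, index=self.expression.columns, name="group")


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def sample_gene_params(config: SimulationConfig) -> GeneParams:
    """Draw per-gene generative parameters reproducibly from the config."""
    rng = _streams(config.seed, 5)[0]
    G = config.n_genes
    m = rng.normal(config.base_mean_loc, config.base_mean_scale, size=G)
    if config.sigma2_fixed is not None:
        sigma2 = np.full(G, float(config.sigma2_fixed))
    else:
        sigma2 = (np.abs(rng.normal(0.0, 1.0, size=G)) + config.sigma_offset) ** 2
    if config.tau2_fixed is not None:
        tau2 = np.full(G, float(config.tau2_fixed))
    else:
        tau2 = (np.abs(rng.normal(0.0, 1.0, size=G)) + config.sigma_offset) ** 2
    if config.effect_kind == "none":
        mu = np.zeros(G)
    elif config.effect_kind == "fixed":
        mu = np.full(G, float(config.effect_value))
    else:
        is_deg = rng.random(G) < config.deg_fraction
        mu = np.where(is_deg, rng.normal(0.0, config.effect_sd, size=G), 0.0)
    return GeneParams(m=m, sigma2=sigma2, mu=mu, tau2=tau2)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one purity-confounded dataset with ground-truth DEG labels."""
    _, rng_x, rng_d, rng_lam, rng_noise = _streams(config.seed, 5)
    params = sample_gene_params(config)
    G, n0, n1 = config.n_genes, config.n_normal, config.n_tumor

    sigma = np.sqrt(params.sigma2)[:, None]
    tau = np.sqrt(params.tau2)[:, None]
    X_normal = params.m[:, None] + sigma * rng_x.standard_normal((G, n0))
    X_tumor = params.m[:, None] + sigma * rng_x.standard_normal((G, n1))
    delta = params.mu[:, None] + tau * rng_d.standard_normal((G, n1))
    Y = X_tumor + delta  # pure tumor signal
    lo, hi = config.purity_range
    lam = rng_lam.uniform(lo, hi, size=n1)
    Y_mixed = lam[None, :] * Y + (1.0 - lam[None, :]) * X_tumor
    if config.purity_noise_sd > 0:
        reported = np.clip(
            lam + rng_noise.normal(0.0, config.purity_noise_sd, size=n1), lo, hi
        )
    else:
        reported = lam.copy()

    genes = pd.Index([f"gene_{i:05d}" for i in range(G)], name="gene_id")
    normal_ids = [f"normal_{j:03d}" for j in range(n0)]
    tumor_ids = [f"tumor_{j:03d}" for j in range(n1)]
    # |m - m'| = |mu| computed directly to avoid cancellation at the boundary
    truth = pd.Series(
        np.abs(params.mu) >= config.delta_threshold,
        index=genes,
        name="is_deg",
    )
    return SimulatedDataset(
        pure_normal=pd.DataFrame(X_normal, index=genes, columns=normal_ids),
        pure_tumor=pd.DataFrame(Y, index=genes, columns=tumor_ids),
        normal_component=pd.DataFrame(X_tumor, index=genes, columns=tumor_ids),
        mixed_tumor=pd.DataFrame(Y_mixed, index=genes, columns=tumor_ids),
        true_purities=pd.Series(lam, index=tumor_ids, name="true_purity"),
        reported_purities=pd.Series(reported, index=tumor_ids, name="reported_purity"),
        truth=truth,
        params=params,
        config=config,
    )


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Write a dataset as TSVs plus a JSON config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.expression.to_csv(outdir / "expression.tsv", sep="\t")
    purity = pd.concat([dataset.true_purities, dataset.reported_purities], axis=1)
    purity.index.name = "sample_id"
    purity.to_csv(outdir / "purity.tsv", sep="\t")
    truth = pd.DataFrame(
        {
            "is_deg": dataset.truth.astype(int),
            "m": dataset.params.m,
            "m_prime": dataset.params.m_prime,
        },
        index=dataset.truth.index,
    )
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    cfg = asdict(dataset.config)
    cfg["purity_range"] = list(cfg["purity_range"])
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")


def read_dataset(indir) -> SimulatedDataset:
    """Re-materialize a dataset written by :func:`write_dataset`.

    Only the observed matrices and the config are stored on disk; the full
    dataset (including the unobservable pure-tumor signal) is recovered by
    re-simulating from the stored config, which is bit-identical because the
    generator is fully seed-driven.
    """
    indir = Path(indir)
    cfg = json.loads((indir / "config.json").read_text())
    cfg["purity_range"] = tuple(cfg["purity_range"])
    return simulate_dataset(SimulationConfig(**cfg))
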