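"""Synthetic clustered NB count matrices for benchmarking.

A scenario is defined by sample size N, gene count G, number of clusters
K, multiplicative shift steps between adjacent clusters on the mean
(``delta_mu``) and dispersion (``delta_theta``) scales, and the fraction
of differentially expressed (DE) genes. Cluster 1 carries the baseline
parameters (mu1, theta1) everywhere; for DE genes cluster k has

    mu_kg = mu1_g * exp((k - 1) * delta_mu)
    theta_kg = theta1_g * exp((k - 1) * delta_theta)

while non-DE genes keep the baseline in every cluster. Sample labels are
drawn i.i.d. uniform over the K clusters (an exact equal split is
available via ``equal_sizes``) and counts are independent NB draws.

Baselines emulate per-gene MLEs from the most variable genes of a bulk
tumor RNA-seq cohort: log-means are drawn from a truncated normal
(median ~50 counts, spanning roughly 1-10^4) and dispersions from a
truncated Gamma(2, 1) on [0.1, 50] — i.e. mostly strongly over-dispersed
genes, as seen after MAD filtering of real tumor data. Both families are
configurable, and user-supplied baseline vectors can be loaded from file.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mixture import ComponentParams
from .preprocessing import CountMatrix

__all__ = [
    "Scenario",
    "BaselineParams",
    "BaselineConfig",
    "GridConfig",
    "sample_baseline",
    "load_baseline",
    "build_cluster_params",
    "simulate_dataset",
    "scenario_grid",
]


@dataclass(frozen=True)
class Scenario:
    """One simulation configuration."""

    n_samples: int
    n_genes: int
    n_clusters: int
    delta_mu: float
    delta_theta: float
    de_fraction: float
    seed: int

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if not (0.0 < self.de_fraction <= 1.0):
            raise ValueError("de_fraction must lie in (0, 1]")
        if self.de_fraction * self.n_genes < 1:
            raise ValueError("de_fraction * n_genes must be >= 1")
        if self.n_samples < 2 or self.n_genes < 1:
            raise ValueError("need n_samples >= 2 and n_genes >= 1")


@dataclass
class BaselineParams:
    """Per-gene baseline NB parameters (mu1, theta1), strictly positive."""

    mu1: np.ndarray
    theta1: np.ndarray

    def __post_init__(self):
        self.mu1 = np.asarray(self.mu1, dtype=float)
        self.theta1 = np.asarray(self.theta1, dtype=float)
        if self.mu1.shape != self.theta1.shape or self.mu1.ndim != 1:
            raise ValueError("mu1 and theta1 must be 1-D vectors of equal length")
        if np.any(~np.isfinite(self.mu1)) or np.any(~np.isfinite(self.theta1)):
            raise ValueError("baseline parameters must be finite")
        if np.any(self.mu1 <= 0) or np.any(self.theta1 <= 0):
            raise ValueError("baseline parameters must be strictly positive")

    @property
    def n_genes(self) -> int:
        return self.mu1.size


@dataclass(frozen=True)
class BaselineConfig:
    """Stand-in distributions for the unpublished real-data baseline MLEs."""

    mu_log_mean: float = float(np.log(50.0))
    mu_log_sd: float = 1.5
    mu_range: tuple[float, float] = (1.0, 1e4)
    theta_shape: float = 2.0
    theta_scale: float = 1.0
    theta_range: tuple[float, float] = (0.1, 50.0)

    def __post_init__(self):
        if self.mu_range[0] >= self.mu_range[1] or self.theta_range[0] >= self.theta_range[1]:
            raise ValueError("ranges must satisfy low < high")
        if self.mu_log_sd <= 0 or self.theta_shape <= 0 or self.theta_scale <= 0:
            raise ValueError("scale/shape parameters must be positive")


def _truncated(draw, low: float, high: float, size: int, rng) -> np.ndarray:
    """Rejection-sample ``size`` values of ``draw(n, rng)`` inside [low, high]."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        batch = draw(max(size - filled, 64), rng)
        keep = batch[(batch >= low) & (batch <= high)]
        take = min(keep.size, size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def sample_baseline(
    n_genes: int,
    seed: int,
    config: BaselineConfig | None = None,
) -> BaselineParams:
    """Draw reproducible per-gene baseline parameters from the stand-in model."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    cfg = config or BaselineConfig()
    rng = np.random.default_rng(seed)
    mu = _truncated(
        lambda n, r: np.exp(r.normal(cfg.mu_log_mean, cfg.mu_log_sd, size=n)),
        *cfg.mu_range,
        n_genes,
        rng,
    )
    theta = _truncated(
        lambda n, r: r.gamma(cfg.theta_shape, cfg.theta_scale, size=n),
        *cfg.theta_range,
        n_genes,
        rng,
    )
    return BaselineParams(mu, theta)


def load_baseline(path, n_genes: int | None = None) -> BaselineParams:
    """Load user-supplied baseline vectors from a CSV with columns mu, theta."""
    df = pd.read_csv(path)
    if not {"mu", "theta"} <= set(df.columns):
        raise ValueError("baseline file must have 'mu' and 'theta' columns")
    base = BaselineParams(df["mu"].to_numpy(float), df["theta"].to_numpy(float))
    if n_genes is not None and base.n_genes != n_genes:
        raise ValueError(f"baseline has {base.n_genes} genes, expected {n_genes}")
    return base


def build_cluster_params(
    base: BaselineParams,
    scenario: Scenario,
    de_mode: str = "subset",
) -> tuple[list[ComponentParams], np.ndarray]:
    """Expand the baseline into K component parameter sets plus the DE index set.

    A seeded random subset of ``ceil(de_fraction * G)`` genes is DE; only
    those genes receive the multiplicative shifts (``de_mode="all"``
    shifts every gene instead). Cluster 1 always equals the baseline.
    """
    if base.n_genes != scenario.n_genes:
        raise ValueError("baseline length does not match scenario n_genes")
    if de_mode not in {"subset", "all"}:
        raise ValueError("de_mode must be 'subset' or 'all'")
    g = scenario.n_genes
    if de_mode == "all":
        de_idx = np.arange(g)
    else:
        n_de = int(np.ceil(scenario.de_fraction * g))
        rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
        de_idx = np.sort(rng.choice(g, size=n_de, replace=False))
    components = []
    for k in range(scenario.n_clusters):
        mu = base.mu1.copy()
        theta = base.theta1.copy()
        mu[de_idx] *= np.exp(k * scenario.delta_mu)
        theta[de_idx] *= np.exp(k * scenario.delta_theta)
        components.append(ComponentParams(mu, theta))
    return components, de_idx


def simulate_dataset(
    scenario: Scenario,
    base: BaselineParams | None = None,
    de_mode: str = "subset",
    equal_sizes: bool = False,
) -> tuple[CountMatrix, np.ndarray]:
    """Generate one clustered count matrix and its true labels (0-based).

    Deterministic given the scenario seed. Labels are i.i.d. uniform over
    clusters unless ``equal_sizes`` requests a shuffled exact split.
    Counts are integer NB draws with the component's (mu, theta).
    """
    if base is None:
        base = sample_baseline(scenario.n_genes, int(np.random.SeedSequence([scenario.seed, 0]).generate_state(1)[0] % 2**31))
    components, _ = build_cluster_params(base, scenario, de_mode=de_mode)
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 2]))
    n, k = scenario.n_samples, scenario.n_clusters
    if equal_sizes:
        labels = np.resize(np.arange(k), n)
        rng.shuffle(labels)
    else:
        labels = rng.integers(0, k, size=n)
    mu = np.stack([c.mu for c in components])[labels]  # N x G
    theta = np.stack([c.theta for c in components])[labels]
    counts = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)
    X = CountMatrix(
        counts,
        [f"S{i + 1:04d}" for i in range(n)],
        [f"g{j + 1:05d}" for j in range(scenario.n_genes)],
    )
    return X, labels


@dataclass(frozen=True)
class GridConfig:
    """Axes of the scenario grid; defaults give the full 480-scenario design."""

    k_values: tuple[int, ...] = (2, 3, 4, 5, 6)
    delta_mu: tuple[float, ...] = (0.1, 0.5, 1.0)
    delta_theta: tuple[float, ...] = (0.0, 1.0)
    de_fractions: tuple[float, ...] = (0.05, 0.10)
    n_samples: tuple[int, ...] = (50, 100, 150, 200)
    n_genes: tuple[int, ...] = (1000, 5000)

    def __post_init__(self):
        for name in ("k_values", "delta_mu", "delta_theta", "de_fractions", "n_samples", "n_genes"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"grid axis {name!r} is empty")


def scenario_grid(config: GridConfig | None = None, master_seed: int = 0) -> list[Scenario]:
    """Enumerate the scenario grid with deterministic per-scenario seeds."""
    cfg = config or GridConfig()
    scenarios = []
    combos = list(
        itertools.product(
            cfg.k_values, cfg.delta_mu, cfg.delta_theta, cfg.de_fractions, cfg.n_samples, cfg.n_genes
        )
    )
    seeds = np.random.SeedSequence(master_seed).generate_state(len(combos)) % 2**31
    for seed, (k, dmu, dth, de, n, g) in zip(seeds, combos, strict=True):
        scenarios.append(
            Scenario(
                n_samples=n,
                n_genes=g,
                n_clusters=k,
                delta_mu=dmu,
                delta_theta=dth,
                de_fraction=de,
                seed=int(seed),
            )
        )
    return scenarios


def write_dataset(X: CountMatrix, labels: np.ndarray, counts_path, labels_path) -> None:
    """Write a simulated dataset as TSV counts plus a CSV label vector."""
    from .preprocessing import write_counts

    write_counts(X, counts_path, format="tsv")
    lines = ["sample_id,label"]
    lines += [f"{sid},{int(lab)}" for sid, lab in zip(X.sample_ids, labels, strict=True)]
    Path(labels_path).write_text("\n".join(lines) + "\n")
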