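"""Negative binomial mixture model fitted by deterministic-annealing EM.

Model
-----
Sample rows ``x_i`` (length G, genes independent) belong to one of K
clusters; within cluster k each gene follows an NB distribution with mean
``mu_kg`` and dispersion ``theta_kg``. The mixture log-likelihood is

    L = sum_i log( sum_k p_k * prod_g f(x_ig | mu_kg, theta_kg) )

Algorithm
---------
* Initialization is deterministic: priors 1/K; component k starts at the
  all-sample per-gene MLE scaled by ``1 + shift*(k-1)`` (a trivial shift,
  default 0.01, that breaks the symmetry which would otherwise pin every
  posterior at 1/K on the first E-step).
* Dispersions stay fixed at their initial (MLE-derived) values; only the
  means and priors are updated, which gives a closed-form M-step.
* The E-step applies deterministic annealing: responsibilities use the
  density raised to the power ``1/tau`` with a temperature ladder
  ``tau_{s+1} = max(1, r * tau_s)`` (defaults tau0=10, r=0.9). Once tau
  reaches 1 the iteration is plain EM and convergence is monitored on the
  relative change in L.
* Before exponentiation the per-sample log joint densities are shifted by
  an offset ``M_i`` (the mean per-gene log density over all components);
  a log-sum-exp pattern on top of that makes posteriors immune to
  underflow even at G = 5000. Posteriors are algebraically invariant to
  the offsets.

The number of clusters is chosen by BIC, ``-2 L + nu log N`` with
``nu = (K - 1) + K * G`` free parameters (dispersions are fixed, hence
not counted); ties go to the smaller K.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import gammaln, logsumexp

from .nb_core import THETA_CAP, THETA_FLOOR, fit_matrix_nb_mle, nb_log_density

__all__ = [
    "ComponentParams",
    "AnnealingSchedule",
    "EMConfig",
    "MixtureModel",
    "ClusteringResult",
    "initialize_params",
    "log_density_matrix",
    "rescale_offsets",
    "e_step",
    "m_step",
    "fit_nbmb",
    "bic",
    "select_k",
    "save_model",
    "write_labels",
]


@dataclass
class ComponentParams:
    """Per-cluster NB parameters: mean and dispersion vectors of length G."""

    mu: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.mu.shape != self.theta.shape or self.mu.ndim != 1:
            raise ValueError("mu and theta must be 1-D vectors of equal length")
        if np.any(self.mu < 0) or np.any(self.theta <= 0):
            raise ValueError("mu must be >= 0 and theta > 0")


@dataclass(frozen=True)
class AnnealingSchedule:
    """Deterministic-annealing temperature ladder tau_{s+1} = max(1, rate*tau_s)."""

    tau0: float = 10.0
    rate: float = 0.9
    floor: float = 1.0

    def __post_init__(self):
        if self.tau0 < self.floor or self.floor < 1.0:
            raise ValueError("need tau0 >= floor >= 1")
        if not (0.0 < self.rate < 1.0):
            raise ValueError("rate must lie in (0, 1)")

    def temperature(self, step: int) -> float:
        return max(self.floor, self.tau0 * self.rate**step)

    @classmethod
    def preset(cls, tau0: float) -> "AnnealingSchedule":
        """The two annealing presets: tau0 = 2 or 10 (rate 0.9)."""
        if tau0 not in (2, 10):
            raise ValueError("presets are tau0 = 2 or 10")
        return cls(tau0=float(tau0))


@dataclass(frozen=True)
class EMConfig:
    max_iter: int = 1000
    tol: float = 1e-6
    init_shift: float = 0.01
    prior_floor: float = 1e-10
    seed: int | None = None  # reserved for multi-start extensions

    def __post_init__(self):
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")
        if not (0.0 <= self.init_shift < 1.0):
            raise ValueError("init_shift must lie in [0, 1)")


@dataclass
class MixtureModel:
    """A fitted NB mixture: parameters, posteriors, likelihood and BIC."""

    K: int
    priors: np.ndarray
    components: list[ComponentParams]
    posteriors: np.ndarray
    loglik: float
    bic: float
    n_iter: int
    labels: np.ndarray
    converged: bool = True
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    tau_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "K": int(self.K),
            "priors": self.priors.tolist(),
            "mu": [c.mu.tolist() for c in self.components],
            "theta": [c.theta.tolist() for c in self.components],
            "loglik": float(self.loglik),
            "bic": float(self.bic),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "labels": self.labels.tolist(),
        }


@dataclass
class ClusteringResult:
    """Outcome of BIC model selection over a range of K."""

    model: MixtureModel
    selected_k: int
    bic_trace: dict[int, float]
    failures: dict[int, str] = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        return self.model.labels

    @property
    def posteriors(self) -> np.ndarray:
        return self.model.posteriors


def _as_values(X) -> np.ndarray:
    values = np.asarray(getattr(X, "values", X), dtype=float)
    if values.ndim != 2:
        raise ValueError("X must be a 2-D samples-by-genes matrix")
    return values


def initialize_params(
    X,
    K: int,
    init_shift: float = 0.01,
    mle: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, list[ComponentParams]]:
    """Deterministic starting point: priors 1/K, MLE scaled by 1+shift*(k-1).

    ``mle`` allows passing precomputed all-sample per-gene (mu, theta)
    estimates so that model selection over several K shares one fit.
    """
    values = _as_values(X)
    n = values.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of samples ({n})")
    mu_mle, theta_mle = mle if mle is not None else fit_matrix_nb_mle(values)
    priors = np.full(K, 1.0 / K)
    components = []
    inside = (theta_mle > THETA_FLOOR) & (theta_mle < THETA_CAP)
    for k in range(K):
        scale = 1.0 + init_shift * k
        theta_k = theta_mle * scale
        out_of_bounds = (theta_k > THETA_CAP) | (theta_k < THETA_FLOOR)
        if np.any(out_of_bounds & inside):
            # genes already pinned at a bound are clipped back silently; a
            # warning only means the shift itself was excessive
            warnings.warn(
                "initial shift pushed dispersions out of bounds; clipping",
                RuntimeWarning,
                stacklevel=2,
            )
        theta_k = np.clip(theta_k, THETA_FLOOR, THETA_CAP)
        components.append(ComponentParams(mu_mle * scale, theta_k))
    return priors, components


def log_density_matrix(X, components: list[ComponentParams]) -> np.ndarray:
    """N x K matrix of per-sample log joint densities (genes summed)."""
    values = _as_values(X)
    out = np.empty((values.shape[0], len(components)))
    for k, comp in enumerate(components):
        if comp.mu.size != values.shape[1]:
            raise ValueError("component dimension does not match matrix")
        out[:, k] = nb_log_density(values, comp.mu[None, :], comp.theta[None, :]).sum(axis=1)
    return out


def rescale_offsets(logdens: np.ndarray, n_genes: int) -> np.ndarray:
    """Per-sample offset M_i = mean per-gene log density over all k and g.

    ``logdens`` holds per-gene sums, so M_i = (row sum) / (K * G).
    Subtracting M_i from each row leaves posteriors unchanged (it cancels
    in the normalization) while keeping the exponentials in range.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    k = logdens.shape[1]
    return logdens.sum(axis=1) / (k * n_genes)


def e_step(
    logdens: np.ndarray,
    priors: np.ndarray,
    offsets: np.ndarray | None = None,
    tau: float = 1.0,
) -> np.ndarray:
    """Annealed responsibilities p_ik ∝ p_k * exp((logdens_ik - M_i) / tau).

    The prior is *not* raised to 1/tau; only the (offset) density is.
    Rows are normalized with log-sum-exp so no intermediate over- or
    underflows even for G = 5000.
    """
    if tau < 1.0:
        raise ValueError("tau must be >= 1")
    z = np.asarray(logdens, dtype=float)
    if offsets is not None:
        z = z - np.asarray(offsets, dtype=float)[:, None]
    z = np.log(np.asarray(priors, dtype=float))[None, :] + z / tau
    bad = ~np.any(np.isfinite(z), axis=1)
    if np.any(bad):
        raise FloatingPointError(
            f"all components have zero density for sample index {int(np.argmax(bad))}"
        )
    return np.exp(z - logsumexp(z, axis=1, keepdims=True))


def m_step(
    X,
    posteriors: np.ndarray,
    prior_floor: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form updates: priors = column means, mu_k = weighted row mean."""
    values = _as_values(X)
    post = np.asarray(posteriors, dtype=float)
    n = values.shape[0]
    colsums = post.sum(axis=0)
    if np.any(colsums < prior_floor * n):
        warnings.warn(
            "degenerate mixture component (posterior mass ~ 0); prior floored",
            RuntimeWarning,
            stacklevel=2,
        )
    priors = np.maximum(colsums / n, prior_floor)
    priors = priors / priors.sum()
    means = (post.T @ values) / np.maximum(colsums, 1e-300)[:, None]
    return priors, means


class _DensityCache:
    """Fast log-density evaluation with fixed dispersions.

    With theta frozen, gammaln(x + theta_k) - gammaln(theta_k) -
    gammaln(x + 1) is constant across EM iterations; only the mu-dependent
    terms change, and those reduce to a matrix-vector product per
    component.
    """

    def __init__(self, values: np.ndarray, components: list[ComponentParams]):
        self.values = values
        self.thetas = [c.theta for c in components]
        self.const = np.empty((values.shape[0], len(components)))
        for k, theta in enumerate(self.thetas):
            self.const[:, k] = (
                gammaln(values + theta[None, :]) - gammaln(theta)[None, :] - gammaln(values + 1.0)
            ).sum(axis=1)

    def logdens(self, means: np.ndarray) -> np.ndarray:
        out = np.empty_like(self.const)
        for k, theta in enumerate(self.thetas):
            mu = np.maximum(means[k], 1e-12)  # ~point mass at 0 for dead genes
            log_denom = np.log(theta + mu)
            a = np.log(mu) - log_denom
            b = float(np.sum(theta * (np.log(theta) - log_denom)))
            out[:, k] = self.const[:, k] + self.values @ a + b
        return out


def fit_nbmb(
    X,
    K: int,
    schedule: AnnealingSchedule | None = None,
    config: EMConfig | None = None,
    mle: tuple[np.ndarray, np.ndarray] | None = None,
) -> MixtureModel:
    """Fit the K-component NB mixture by deterministic-annealing EM.

    The annealing ladder always runs to tau = 1; convergence (relative
    change in L below ``config.tol``) is only tested in the tau = 1 phase.
    The returned posteriors, labels, L and BIC are evaluated at tau = 1
    with the final parameters. Fully deterministic given its inputs.
    """
    schedule = schedule or AnnealingSchedule()
    config = config or EMConfig()
    values = _as_values(X)
    n, g = values.shape
    priors, components = initialize_params(X, K, config.init_shift, mle=mle)
    cache = _DensityCache(values, components)
    means = np.stack([c.mu for c in components])

    loglik_trace: list[float] = []
    tau_trace: list[float] = []
    prev_loglik = None
    converged = False
    n_iter = 0
    for step in range(config.max_iter):
        tau = schedule.temperature(step)
        logdens = cache.logdens(means)
        offsets = rescale_offsets(logdens, g)
        loglik = float(np.sum(logsumexp(np.log(priors)[None, :] + logdens, axis=1)))
        loglik_trace.append(loglik)
        tau_trace.append(tau)
        n_iter = step + 1
        if tau == 1.0 and prev_loglik is not None:
            if abs(loglik - prev_loglik) / (abs(prev_loglik) + 1.0) < config.tol:
                converged = True
                break
        prev_loglik = loglik if tau == 1.0 else None
        posteriors = e_step(logdens, priors, offsets, tau)
        priors, means = m_step(values, posteriors, config.prior_floor)

    if not converged:
        warnings.warn(
            f"EM did not converge in {config.max_iter} iterations (K={K})",
            RuntimeWarning,
            stacklevel=2,
        )
    components = [ComponentParams(means[k], components[k].theta) for k in range(K)]
    logdens = cache.logdens(means)
    offsets = rescale_offsets(logdens, g)
    posteriors = e_step(logdens, priors, offsets, tau=1.0)
    loglik = float(np.sum(logsumexp(np.log(priors)[None, :] + logdens, axis=1)))
    labels = np.argmax(posteriors, axis=1)
    model = MixtureModel(
        K=K,
        priors=priors,
        components=components,
        posteriors=posteriors,
        loglik=loglik,
        bic=np.nan,
        n_iter=n_iter,
        labels=labels,
        converged=converged,
        loglik_trace=np.asarray(loglik_trace),
        tau_trace=np.asarray(tau_trace),
    )
    model.bic = bic(model, n)
    return model


def bic(model: MixtureModel, n_samples: int, count_dispersions: bool = False) -> float:
    """BIC = -2 L + nu log N; lower is better.

    By default nu = (K - 1) + K*G: mixing proportions plus component
    means. Dispersions are fixed after initialization and therefore not
    counted as free parameters; ``count_dispersions=True`` adds K*G for
    sensitivity checks.
    """
    g = model.components[0].mu.size
    nu = (model.K - 1) + model.K * g
    if count_dispersions:
        nu += model.K * g
    return -2.0 * model.loglik + nu * np.log(n_samples)


def select_k(
    X,
    k_range,
    schedule: AnnealingSchedule | None = None,
    config: EMConfig | None = None,
) -> ClusteringResult:
    """Fit every K in ``k_range`` and keep the fit with minimal BIC.

    Ties are broken toward the smaller K. The all-sample per-gene MLE is
    computed once and shared across candidate fits. A failure at one K is
    recorded and skipped; if every K fails an error is raised.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1:
        raise ValueError("k_range must be a non-empty collection of integers >= 1")
    values = _as_values(X)
    mle = fit_matrix_nb_mle(values)
    trace: dict[int, float] = {}
    failures: dict[int, str] = {}
    best: MixtureModel | None = None
    for k in ks:
        try:
            model = fit_nbmb(values, k, schedule=schedule, config=config, mle=mle)
        except Exception as exc:  # noqa: BLE001 - record and move on
            failures[k] = str(exc)
            warnings.warn(f"fit failed for K={k}: {exc}", RuntimeWarning, stacklevel=2)
            continue
        trace[k] = model.bic
        if best is None or model.bic < best.bic:
            best = model
    if best is None:
        raise RuntimeError(f"all candidate fits failed: {failures}")
    return ClusteringResult(model=best, selected_k=best.K, bic_trace=trace, failures=failures)


def save_model(model: MixtureModel, path) -> None:
    """Serialize a fitted model to JSON."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def write_labels(labels, sample_ids, path) -> None:
    """Write hard assignments as two-column CSV (sample_id, cluster)."""
    lines = ["sample_id,cluster"]
    lines += [f"{sid},{int(lab)}" for sid, lab in zip(sample_ids, labels, strict=True)]
    Path(path).write_text("\n".join(lines) + "\n")
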