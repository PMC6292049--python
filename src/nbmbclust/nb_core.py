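"""Negative binomial density and per-gene maximum-likelihood estimation.

The negative binomial (NB) distribution is parameterized throughout by its
mean ``mu`` and size/dispersion ``theta``, with variance
``mu + mu**2 / theta``; ``theta -> inf`` recovers the Poisson distribution.
RNA-seq counts that have been library-size normalized (e.g. CPM) are
continuous, so the factorial in the NB probability mass function is
generalized to ``Gamma(x + 1)`` and all evaluation happens in log space
via log-gamma functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

__all__ = [
    "THETA_FLOOR",
    "THETA_CAP",
    "GeneNBEstimate",
    "nb_log_density",
    "fit_gene_nb_mle",
    "fit_matrix_nb_mle",
]

#: Default bounds for the dispersion parameter. The cap encodes the Poisson
#: limit (an estimate at the cap means the data show no over-dispersion).
THETA_FLOOR = 1e-3
THETA_CAP = 1e5


@dataclass(frozen=True)
class GeneNBEstimate:
    """Per-gene NB maximum-likelihood estimate.

    Attributes
    ----------
    mu_hat : float
        MLE of the NB mean; equals the sample mean.
    theta_hat : float
        MLE of the NB size parameter, constrained to
        ``[theta_floor, theta_cap]``. Larger values mean less dispersion.
    converged : bool
        Whether the 1-D optimizer reported success.
    at_cap : bool
        True when the data are under-dispersed (sample variance <= mean)
        or the optimizer ran into the upper cap; the gene is then
        effectively Poisson.
    """

    mu_hat: float
    theta_hat: float
    converged: bool
    at_cap: bool


def _validate(name: str, arr: np.ndarray, *, nonneg: bool = True, positive: bool = False) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if positive:
        if np.any(arr <= 0):
            raise ValueError(f"{name} must be strictly positive")
    elif nonneg and np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")


def nb_log_density(x, mu, theta):
    """Log of the NB density ``f(x | mu, theta)``, elementwise.

    ``x`` need not be an integer: the factorial is generalized to
    ``Gamma(x + 1)`` so that normalized (continuous) counts are supported.
    A zero-mean gene is treated as a point mass at zero: the log density
    is 0 at ``x == 0`` and ``-inf`` otherwise.

    Parameters broadcast against each other; scalars in, scalar out.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    _validate("x", x)
    _validate("mu", mu)
    _validate("theta", theta, positive=True)

    x, mu, theta = np.broadcast_arrays(x, mu, theta)
    mu_safe = np.where(mu > 0, mu, 1.0)
    log_denom = np.log(theta + mu_safe)
    out = (
        gammaln(x + theta)
        - gammaln(theta)
        - gammaln(x + 1.0)
        + x * (np.log(mu_safe) - log_denom)
        + theta * (np.log(theta) - log_denom)
    )
    out = np.where(mu > 0, out, np.where(x == 0, 0.0, -np.inf))
    return float(out) if out.ndim == 0 else out


def nb_profile_loglik(theta: float, x: np.ndarray) -> float:
    """Profile log-likelihood of ``theta`` with the mean fixed at ``mean(x)``."""
    x = np.asarray(x, dtype=float)
    return float(np.sum(nb_log_density(x, x.mean(), theta)))


def fit_gene_nb_mle(
    x,
    theta_bounds: tuple[float, float] = (THETA_FLOOR, THETA_CAP),
    xatol: float = 1e-8,
) -> GeneNBEstimate:
    """Exact MLE of (mu, theta) for one gene across all samples.

    The mean MLE is the sample mean. The dispersion maximizes the profile
    log-likelihood over ``log(theta)`` with a bounded scalar optimizer.
    Under-dispersed input (sample variance <= mean, which includes
    constant and all-zero vectors) pins ``theta_hat`` at the cap.
    """
    x = np.asarray(x, dtype=float)
    _validate("x", x)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("x must be a 1-D vector of length >= 2")
    lo, hi = theta_bounds
    if not (0 < lo < hi):
        raise ValueError("theta_bounds must satisfy 0 < floor < cap")

    mu_hat = float(x.mean())
    if mu_hat == 0.0 or x.var(ddof=1) <= mu_hat:
        return GeneNBEstimate(mu_hat, hi, True, True)

    res = minimize_scalar(
        lambda log_t: -nb_profile_loglik(float(np.exp(log_t)), x),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": xatol},
    )
    theta_hat = float(np.clip(np.exp(res.x), lo, hi))
    at_cap = theta_hat >= hi * (1.0 - 1e-6)
    return GeneNBEstimate(mu_hat, theta_hat, bool(res.success), at_cap)


def fit_matrix_nb_mle(X, theta_bounds: tuple[float, float] = (THETA_FLOOR, THETA_CAP)):
    """Column-wise NB MLE over a samples-by-genes matrix.

    Genes are treated as independent. Accepts a ``CountMatrix`` or a plain
    2-D array and returns ``(mu_hat, theta_hat)`` as length-G vectors.
    """
    values = np.asarray(getattr(X, "values", X), dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with >= 2 samples")
    n_genes = values.shape[1]
    mu = np.empty(n_genes)
    theta = np.empty(n_genes)
    for g in range(n_genes):
        est = fit_gene_nb_mle(values[:, g], theta_bounds=theta_bounds)
        mu[g] = est.mu_hat
        theta[g] = est.theta_hat
    return mu, theta
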