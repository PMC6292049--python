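"""Clustering evaluation: ARI, Gaussian-mixture comparators, study driver.

The adjusted Rand index (Hubert-Arabie) is implemented directly from the
pairwise contingency table so that it can be cross-checked against both
an exhaustive pair-counting oracle and an independent library routine.
Gaussian-mixture comparators mirror the standard workflow: an optional
per-element or per-gene transform (log / Blom), an EM Gaussian mixture
with diagonal per-component covariances fitted for each candidate K, and
BIC selection. The study driver simulates replicate datasets per
scenario, runs each requested method with BIC-selected K, and aggregates
ARI against the true labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import comb
from sklearn.mixture import GaussianMixture

from .mixture import AnnealingSchedule, ClusteringResult, EMConfig, MixtureModel, select_k
from .preprocessing import CountMatrix, blom_transform, log_transform
from .simulate import Scenario, sample_baseline, simulate_dataset

__all__ = [
    "ScenarioResult",
    "adjusted_rand_index",
    "gmm_cluster",
    "run_simulation_study",
    "summarize_results",
    "METHODS",
]

METHODS = ("NBMB", "GMM-none", "GMM-log", "GMM-blom")


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    Chance-corrected pair-counting agreement: 1 for identical partitions
    (up to relabeling), ~0 for independent ones. When both partitions are
    a single cluster the index is 1 by convention (the denominator of the
    adjusted form vanishes).
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.size != b.size:
        raise ValueError("label vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(table, (ai, bi), 1)
    index = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((index - expected) / (max_index - expected))


def gmm_cluster(
    X,
    transform: str = "none",
    k_range=(2, 3, 4, 5, 6),
    covariance_mode: str = "diag",
    seed: int = 0,
    reg_covar: float = 1e-6,
) -> ClusteringResult:
    """Gaussian-mixture clustering with an optional transform and BIC over K.

    ``transform`` is one of none / log / blom. The mixture fit is
    delegated to scikit-learn's EM implementation; the contract here is
    only transform -> fit per K -> BIC select (ties to smaller K) ->
    labels. Diagonal per-component covariances are the default because
    G >> N makes full covariances singular.
    """
    if transform not in {"none", "log", "blom"}:
        raise ValueError("transform must be one of: none, log, blom")
    if not isinstance(X, CountMatrix):
        X = CountMatrix(np.asarray(X, dtype=float), allow_negative=True)
    if transform == "log":
        X = log_transform(X)
    elif transform == "blom":
        X = blom_transform(X)
    values = X.values

    ks = sorted(set(int(k) for k in k_range))
    trace: dict[int, float] = {}
    failures: dict[int, str] = {}
    best_gm = None
    best_k = None
    best_bic = np.inf
    for k in ks:
        gm = GaussianMixture(
            n_components=k,
            covariance_type=covariance_mode,
            random_state=seed,
            n_init=1,
            reg_covar=reg_covar,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(values)
            k_bic = float(gm.bic(values))
        except Exception as exc:  # noqa: BLE001 - degenerate fit, skip this K
            failures[k] = str(exc)
            warnings.warn(f"GMM fit failed for K={k}: {exc}", RuntimeWarning, stacklevel=2)
            continue
        trace[k] = k_bic
        if k_bic < best_bic:
            best_bic, best_gm, best_k = k_bic, gm, k
    if best_gm is None:
        raise RuntimeError(f"all GMM fits failed: {failures}")
    posteriors = best_gm.predict_proba(values)
    labels = np.argmax(posteriors, axis=1)
    model = MixtureModel(
        K=best_k,
        priors=best_gm.weights_,
        components=[],
        posteriors=posteriors,
        loglik=float(best_gm.score(values) * values.shape[0]),
        bic=best_bic,
        n_iter=int(best_gm.n_iter_),
        labels=labels,
        converged=bool(best_gm.converged_),
    )
    return ClusteringResult(model=model, selected_k=best_k, bic_trace=trace, failures=failures)


@dataclass
class ScenarioResult:
    """Per-scenario, per-method replicate ARIs and selected K values."""

    scenario: Scenario
    method: str
    aris: np.ndarray
    selected_ks: np.ndarray
    n_failed: int = 0
    failure_messages: list[str] = field(default_factory=list)

    @property
    def mean_ari(self) -> float:
        return float(np.mean(self.aris)) if self.aris.size else float("nan")

    @property
    def sd_ari(self) -> float:
        return float(np.std(self.aris, ddof=1)) if self.aris.size > 1 else float("nan")

    @property
    def median_ari(self) -> float:
        return float(np.median(self.aris)) if self.aris.size else float("nan")


def _sub_seed(master_seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([master_seed, *key]).generate_state(1)[0] % 2**31)


def run_simulation_study(
    scenarios,
    n_replicates: int,
    methods=METHODS,
    master_seed: int = 0,
    k_range=(2, 3, 4, 5, 6),
    schedule: AnnealingSchedule | None = None,
    config: EMConfig | None = None,
) -> list[ScenarioResult]:
    """Simulate replicates per scenario and score each method by ARI.

    Every replicate draws a fresh baseline and dataset from seeds derived
    deterministically from ``master_seed``, so results are reproducible
    and independent of execution order. Per-replicate failures are
    recorded, excluded from the summaries and counted.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    results = []
    for s_idx, scenario in enumerate(scenarios):
        per_method: dict[str, dict[str, list]] = {
            m: {"ari": [], "k": [], "fail": []} for m in methods
        }
        for rep in range(n_replicates):
            rep_seed = _sub_seed(master_seed, s_idx, rep)
            base = sample_baseline(scenario.n_genes, _sub_seed(rep_seed, 101))
            rep_scenario = Scenario(
                n_samples=scenario.n_samples,
                n_genes=scenario.n_genes,
                n_clusters=scenario.n_clusters,
                delta_mu=scenario.delta_mu,
                delta_theta=scenario.delta_theta,
                de_fraction=scenario.de_fraction,
                seed=rep_seed,
            )
            X, truth = simulate_dataset(rep_scenario, base)
            for method in methods:
                try:
                    if method == "NBMB":
                        res = select_k(X, k_range, schedule=schedule, config=config)
                    else:
                        res = gmm_cluster(
                            X,
                            transform=method.split("-", 1)[1],
                            k_range=k_range,
                            seed=rep_seed,
                        )
                except Exception as exc:  # noqa: BLE001 - recorded, run continues
                    per_method[method]["fail"].append(f"rep {rep}: {exc}")
                    continue
                per_method[method]["ari"].append(adjusted_rand_index(truth, res.labels))
                per_method[method]["k"].append(res.selected_k)
        for method in methods:
            rec = per_method[method]
            results.append(
                ScenarioResult(
                    scenario=scenario,
                    method=method,
                    aris=np.asarray(rec["ari"], dtype=float),
                    selected_ks=np.asarray(rec["k"], dtype=int),
                    n_failed=len(rec["fail"]),
                    failure_messages=rec["fail"],
                )
            )
    return results


def summarize_results(results) -> pd.DataFrame:
    """Long-format summary keyed by scenario axes and method."""
    if not results:
        raise ValueError("no results to summarize")
    rows = []
    for res in results:
        s = res.scenario
        ks = res.selected_ks
        modal_k = int(pd.Series(ks).mode().iloc[0]) if ks.size else -1
        rows.append(
            {
                "N": s.n_samples,
                "G": s.n_genes,
                "K_true": s.n_clusters,
                "delta_mu": s.delta_mu,
                "delta_theta": s.delta_theta,
                "de_fraction": s.de_fraction,
                "method": res.method,
                "n_replicates": int(res.aris.size),
                "n_failed": res.n_failed,
                "mean_ari": res.mean_ari,
                "sd_ari": res.sd_ari,
                "median_ari": res.median_ari,
                "min_ari": float(res.aris.min()) if res.aris.size else float("nan"),
                "max_ari": float(res.aris.max()) if res.aris.size else float("nan"),
                "modal_k": modal_k,
            }
        )
    return pd.DataFrame(rows)
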