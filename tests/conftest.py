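import itertools

import numpy as np
import pytest

from nbmbclust import BaselineParams, Scenario, sample_baseline, simulate_dataset


def ari_pair_counting(a, b) -> float:
    """Brute-force adjusted Rand index by enumerating all sample pairs.

    Independent oracle: counts agreeing/disagreeing pairs directly and
    applies the chance correction from the pair totals.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    n = a.size
    together_a = together_b = together_both = 0
    for i, j in itertools.combinations(range(n), 2):
        sa = a[i] == a[j]
        sb = b[i] == b[j]
        together_a += sa
        together_b += sb
        together_both += sa and sb
    n_pairs = n * (n - 1) // 2
    expected = together_a * together_b / n_pairs
    max_index = 0.5 * (together_a + together_b)
    if max_index == expected:
        return 1.0
    return (together_both - expected) / (max_index - expected)


@pytest.fixture
def two_cluster_data():
    """Well-separated two-cluster NB dataset with known truth."""
    scenario = Scenario(
        n_samples=60,
        n_genes=50,
        n_clusters=2,
        delta_mu=2.0,
        delta_theta=0.0,
        de_fraction=1.0,
        seed=7,
    )
    base = sample_baseline(50, seed=3)
    X, truth = simulate_dataset(scenario, base)
    return X, truth


@pytest.fixture
def flat_baseline():
    return BaselineParams(np.full(10, 10.0), np.full(10, 2.0))
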