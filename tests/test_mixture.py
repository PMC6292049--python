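"""NB mixture EM: initialization, E/M steps, annealing, BIC, selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nbmbclust import (
    AnnealingSchedule,
    ComponentParams,
    EMConfig,
    adjusted_rand_index,
    bic,
    fit_nbmb,
    select_k,
)
from nbmbclust.mixture import (
    e_step,
    initialize_params,
    log_density_matrix,
    m_step,
    rescale_offsets,
)
from nbmbclust.nb_core import fit_matrix_nb_mle, nb_log_density


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(11)
    return rng.negative_binomial(2, 2 / 12, size=(20, 5)).astype(float)


class TestInitialization:
    def test_k1_is_plain_mle(self, small_matrix):
        priors, comps = initialize_params(small_matrix, 1)
        mu_mle, theta_mle = fit_matrix_nb_mle(small_matrix)
        np.testing.assert_allclose(priors, [1.0])
        np.testing.assert_allclose(comps[0].mu, mu_mle)
        np.testing.assert_allclose(comps[0].theta, theta_mle)

    def test_shift_step(self):
        # mu_k = mu_mle * (1 + 0.01*(k-1)): 100 -> 100, 101, 102
        X = np.array([[90.0], [110.0], [130.0], [70.0]])  # mean 100
        priors, comps = initialize_params(X, 3, init_shift=0.01)
        np.testing.assert_allclose(priors, [1 / 3] * 3)
        np.testing.assert_allclose([c.mu[0] for c in comps], [100.0, 101.0, 102.0])

    def test_zero_shift_gives_uniform_posteriors(self, small_matrix):
        priors, comps = initialize_params(small_matrix, 2, init_shift=0.0)
        logdens = log_density_matrix(small_matrix, comps)
        post = e_step(logdens, priors, rescale_offsets(logdens, 5), tau=1.0)
        np.testing.assert_allclose(post, 0.5, atol=1e-12)

    def test_k_exceeding_n_raises(self, small_matrix):
        with pytest.raises(ValueError):
            initialize_params(small_matrix, 21)


class TestLogDensityMatrix:
    def test_single_gene_closed_form(self):
        comps = [ComponentParams([1.0], [1.0])] * 2
        ld = log_density_matrix(np.array([[0.0]]), comps)
        np.testing.assert_allclose(ld, np.log(0.5))

    def test_identical_components_equal_columns(self, small_matrix):
        _, comps = initialize_params(small_matrix, 3, init_shift=0.0)
        ld = log_density_matrix(small_matrix, comps)
        np.testing.assert_allclose(ld[:, 0], ld[:, 1])
        np.testing.assert_allclose(ld[:, 0], ld[:, 2])

    def test_matches_per_element_sum(self):
        rng = np.random.default_rng(3)
        X = rng.negative_binomial(2, 0.3, size=(3, 2)).astype(float)
        comps = [
            ComponentParams([4.0, 8.0], [1.5, 3.0]),
            ComponentParams([6.0, 2.0], [0.7, 5.0]),
        ]
        ld = log_density_matrix(X, comps)
        for i in range(3):
            for k, c in enumerate(comps):
                brute = sum(
                    nb_log_density(X[i, g], c.mu[g], c.theta[g]) for g in range(2)
                )
                assert ld[i, k] == pytest.approx(brute, abs=1e-12)


class TestRescaleAndEStep:
    def test_offset_examples(self):
        assert rescale_offsets(np.array([[-7.5]]), 1)[0] == -7.5
        assert rescale_offsets(np.array([[-10.0, -20.0]]), 1)[0] == -15.0

    @pytest.mark.parametrize("tau, expected", [(1.0, 0.8807970779778823), (2.0, 0.7310585786300049)])
    def test_two_component_closed_form(self, tau, expected):
        logdens = np.array([[-10.0, -12.0]])
        post = e_step(logdens, np.array([0.5, 0.5]), np.zeros(1), tau=tau)
        assert post[0, 0] == pytest.approx(expected, abs=1e-12)
        assert post[0, 1] == pytest.approx(1 - expected, abs=1e-12)

    def test_annealing_flattens(self):
        logdens = np.array([[-10.0, -12.0]])
        p1 = e_step(logdens, np.array([0.5, 0.5]), tau=1.0)
        p2 = e_step(logdens, np.array([0.5, 0.5]), tau=2.0)
        assert p2[0, 0] < p1[0, 0]

    @pytest.mark.parametrize("tau", [1.0, 2.0])
    def test_offsets_cancel(self, tau):
        rng = np.random.default_rng(8)
        logdens = rng.normal(-500, 50, size=(10, 3))
        priors = np.array([0.2, 0.3, 0.5])
        offsets = rescale_offsets(logdens, 25)
        with_off = e_step(logdens, priors, offsets, tau=tau)
        without = e_step(logdens, priors, None, tau=tau)
        np.testing.assert_allclose(with_off, without, atol=1e-12)

    def test_all_minus_inf_row_raises(self):
        logdens = np.array([[-np.inf, -np.inf]])
        with pytest.raises(FloatingPointError, match="sample index 0"):
            e_step(logdens, np.array([0.5, 0.5]))

    @settings(deadline=None, max_examples=50)
    @given(
        logdens=arrays(float, (6, 3), elements=st.floats(-2000, 0)),
        tau=st.floats(1.0, 10.0),
    )
    def test_rows_sum_to_one(self, logdens, tau):
        post = e_step(logdens, np.array([0.5, 0.25, 0.25]), tau=tau)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(post >= 0)


class TestMStep:
    def test_uniform_posteriors_give_grand_mean(self, small_matrix):
        post = np.full((20, 3), 1 / 3)
        priors, means = m_step(small_matrix, post)
        np.testing.assert_allclose(priors, 1 / 3)
        for k in range(3):
            np.testing.assert_allclose(means[k], small_matrix.mean(axis=0))

    def test_hard_posteriors_give_group_means(self, small_matrix):
        post = np.zeros((20, 2))
        post[:12, 0] = 1.0
        post[12:, 1] = 1.0
        priors, means = m_step(small_matrix, post)
        np.testing.assert_allclose(priors, [0.6, 0.4])
        np.testing.assert_allclose(means[0], small_matrix[:12].mean(axis=0))
        np.testing.assert_allclose(means[1], small_matrix[12:].mean(axis=0))

    def test_weighted_mean_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 10, size=(4, 2))
        post = rng.dirichlet([1.0, 1.0], size=4)
        _, means = m_step(X, post)
        for k in range(2):
            for g in range(2):
                expected = sum(post[i, k] * X[i, g] for i in range(4)) / post[:, k].sum()
                assert means[k, g] == pytest.approx(expected, abs=1e-12)

    def test_empty_component_warns(self, small_matrix):
        post = np.zeros((20, 2))
        post[:, 0] = 1.0
        with pytest.warns(RuntimeWarning, match="degenerate"):
            priors, _ = m_step(small_matrix, post)
        assert priors.sum() == pytest.approx(1.0)
        assert np.all(priors > 0)


def tau1_trace(model):
    return model.loglik_trace[model.tau_trace == 1.0]


class TestFitNBMB:
    def test_separated_clusters_recovered(self, two_cluster_data):
        X, truth = two_cluster_data
        model = fit_nbmb(X, 2)
        assert adjusted_rand_index(truth, model.labels) == 1.0
        # recovered means within 10% of the truth for each matched component
        from nbmbclust import build_cluster_params, sample_baseline, Scenario

        base = sample_baseline(50, seed=3)
        scenario = Scenario(60, 50, 2, 2.0, 0.0, 1.0, 7)
        comps_true, _ = build_cluster_params(base, scenario)
        order = np.argsort([c.mu.mean() for c in model.components])
        for k, true_c in zip(order, comps_true, strict=True):
            rel = np.abs(model.components[k].mu - true_c.mu) / true_c.mu
            assert np.median(rel) < 0.10

    def test_monotone_loglik_at_tau1(self, two_cluster_data):
        X, _ = two_cluster_data
        model = fit_nbmb(X, 3)
        trace = tau1_trace(model)
        assert trace.size >= 2
        assert np.all(np.diff(trace) >= -1e-8 * (np.abs(trace[:-1]) + 1))

    def test_no_annealing_monotone_from_start(self, two_cluster_data):
        X, _ = two_cluster_data
        model = fit_nbmb(X, 2, schedule=AnnealingSchedule(tau0=1.0, rate=0.9))
        diffs = np.diff(model.loglik_trace)
        assert np.all(diffs >= -1e-8 * (np.abs(model.loglik_trace[:-1]) + 1))

    def test_k1_collapses_to_single_component(self, small_matrix):
        model = fit_nbmb(small_matrix, 1)
        assert model.K == 1
        np.testing.assert_allclose(model.priors, [1.0])
        np.testing.assert_allclose(model.posteriors, 1.0)
        # single-component EM fixed point: mean = grand mean
        np.testing.assert_allclose(model.components[0].mu, small_matrix.mean(axis=0))

    def test_posterior_rows_sum_to_one(self, two_cluster_data):
        X, _ = two_cluster_data
        model = fit_nbmb(X, 3)
        np.testing.assert_allclose(model.posteriors.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(model.priors.sum(), 1.0, atol=1e-10)
        np.testing.assert_array_equal(model.labels, np.argmax(model.posteriors, axis=1))

    def test_deterministic(self, two_cluster_data):
        X, _ = two_cluster_data
        m1 = fit_nbmb(X, 2)
        m2 = fit_nbmb(X, 2)
        np.testing.assert_array_equal(m1.labels, m2.labels)
        assert m1.loglik == m2.loglik

    def test_sample_permutation_permutes_labels(self, two_cluster_data):
        X, _ = two_cluster_data
        rng = np.random.default_rng(0)
        perm = rng.permutation(X.n_samples)
        m = fit_nbmb(X.values, 2)
        mp = fit_nbmb(X.values[perm], 2)
        np.testing.assert_array_equal(mp.labels, m.labels[perm])

    def test_gene_permutation_leaves_labels(self, two_cluster_data):
        X, _ = two_cluster_data
        rng = np.random.default_rng(1)
        perm = rng.permutation(X.n_genes)
        m = fit_nbmb(X.values, 2)
        mp = fit_nbmb(X.values[:, perm], 2)
        np.testing.assert_array_equal(mp.labels, m.labels)


class TestBICAndSelection:
    def test_bic_formula(self):
        from nbmbclust.mixture import MixtureModel

        model = MixtureModel(
            K=1,
            priors=np.array([1.0]),
            components=[ComponentParams([1.0], [1.0])],
            posteriors=np.ones((10, 1)),
            loglik=-100.0,
            bic=np.nan,
            n_iter=1,
            labels=np.zeros(10, dtype=int),
        )
        assert bic(model, 10) == pytest.approx(200 + 1 * np.log(10))
        model2 = MixtureModel(
            K=2,
            priors=np.array([0.5, 0.5]),
            components=[ComponentParams([1.0], [1.0])] * 2,
            posteriors=np.full((10, 2), 0.5),
            loglik=-100.0,
            bic=np.nan,
            n_iter=1,
            labels=np.zeros(10, dtype=int),
        )
        assert bic(model2, 10) == pytest.approx(200 + 3 * np.log(10))
        assert bic(model2, 10) > bic(model, 10)
        assert bic(model2, 10, count_dispersions=True) == pytest.approx(200 + 5 * np.log(10))

    def test_bic_prefers_true_k2(self, two_cluster_data):
        X, _ = two_cluster_data
        m1 = fit_nbmb(X, 1)
        m2 = fit_nbmb(X, 2)
        assert m2.bic < m1.bic

    def test_singleton_range(self, two_cluster_data):
        X, _ = two_cluster_data
        res = select_k(X, [2])
        assert res.selected_k == 2
        assert set(res.bic_trace) == {2}

    def test_three_clusters_selected(self):
        from nbmbclust import Scenario, sample_baseline, simulate_dataset

        scenario = Scenario(90, 60, 3, 1.5, 0.0, 1.0, 13)
        X, truth = simulate_dataset(scenario, sample_baseline(60, 14))
        res = select_k(X, range(2, 6))
        assert res.selected_k == 3
        assert adjusted_rand_index(truth, res.labels) > 0.9

    def test_reversed_range_same_k(self, two_cluster_data):
        X, _ = two_cluster_data
        fwd = select_k(X, [2, 3, 4])
        rev = select_k(X, [4, 3, 2])
        assert fwd.selected_k == rev.selected_k
        assert fwd.bic_trace == rev.bic_trace

    def test_tie_breaks_to_smaller_k(self, two_cluster_data, monkeypatch):
        # Force equal BICs for every candidate: the smaller K must win.
        import nbmbclust.mixture as mx

        X, _ = two_cluster_data
        real_fit = mx.fit_nbmb

        def tied_fit(values, k, **kwargs):
            model = real_fit(values, k, **kwargs)
            model.bic = 1234.5
            return model

        monkeypatch.setattr(mx, "fit_nbmb", tied_fit)
        res = mx.select_k(X, [2, 3, 4])
        assert res.selected_k == 2


class TestConfigValidation:
    def test_schedule_invariants(self):
        sched = AnnealingSchedule(tau0=10.0, rate=0.9)
        temps = [sched.temperature(s) for s in range(60)]
        assert all(t2 <= t1 for t1, t2 in zip(temps[:-1], temps[1:], strict=True))
        assert temps[-1] == 1.0
        with pytest.raises(ValueError):
            AnnealingSchedule(tau0=0.5)
        with pytest.raises(ValueError):
            AnnealingSchedule(rate=1.5)
        assert AnnealingSchedule.preset(2).tau0 == 2.0

    def test_emconfig_invariants(self):
        with pytest.raises(ValueError):
            EMConfig(tol=0.0)
        with pytest.raises(ValueError):
            EMConfig(init_shift=1.5)
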