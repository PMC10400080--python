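import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import brainstates as bs
from brainstates.hmm_core import CH_CAP

from conftest import random_hmm_instance


# ---------------------------------------------------------------------------
# brute-force oracles, independent of the implementation under test
# ---------------------------------------------------------------------------


def path_logprob(params, data, path):
    lp = np.log(params.initial[path[0]])
    lp += multivariate_normal.logpdf(data[0], params.means[path[0]], params.covariances[path[0]])
    for t in range(1, len(path)):
        lp += np.log(params.transition[path[t - 1], path[t]])
        lp += multivariate_normal.logpdf(
            data[t], params.means[path[t]], params.covariances[path[t]]
        )
    return lp


def enumerate_paths(params, data):
    T = data.shape[0]
    paths = list(itertools.product(range(params.K), repeat=T))
    logps = np.array([path_logprob(params, data, p) for p in paths])
    return paths, logps


class TestKMeansInit:
    def test_two_separated_clouds(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(100, 2)) + [10, 0]
        b = rng.normal(size=(100, 2)) - [10, 0]
        data = np.vstack([a, b])
        params = bs.kmeans_init(data, K=2, seed=1)
        perm = bs.match_states(params.means, np.array([[10.0, 0.0], [-10.0, 0.0]]))
        matched = bs.relabel(params, perm)
        np.testing.assert_allclose(matched.means[0], a.mean(0), atol=0.05)
        np.testing.assert_allclose(matched.means[1], b.mean(0), atol=0.05)
        params.validate()

    def test_k1_is_grand_mean(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(50, 3))
        params = bs.kmeans_init(data, K=1, seed=2)
        np.testing.assert_allclose(params.means[0], data.mean(0), atol=1e-12)
        np.testing.assert_allclose(params.transition, [[1.0]])

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(80, 3))
        a = bs.kmeans_init(data, K=3, seed=5)
        b = bs.kmeans_init(data, K=3, seed=5)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.transition, b.transition)


class TestForwardBackward:
    def test_k1_posterior_trivial_and_loglik_exact(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(20, 2))
        mu = data.mean(0)
        cov = np.cov(data.T) + 1e-6 * np.eye(2)
        params = bs.HMMParameters(mu[None], cov[None], [[1.0]], [1.0])
        post, _, ll = bs.forward_backward(data, params)
        np.testing.assert_allclose(post.gamma, 1.0)
        expect = multivariate_normal.logpdf(data, mu, cov).sum()
        np.testing.assert_allclose(ll, expect, rtol=1e-10)

    def test_matches_path_enumeration_posterior(self):
        # gamma from summing over all K^T enumerated paths, K=2, T=3
        rng = np.random.default_rng(4)
        for _ in range(5):
            params, data = random_hmm_instance(rng, K=2, T=3)
            paths, logps = enumerate_paths(params, data)
            w = np.exp(logps - logps.max())
            w /= w.sum()
            expect = np.zeros((3, 2))
            for p, wi in zip(paths, w):
                for t, s in enumerate(p):
                    expect[t, s] += wi
            post, _, ll = bs.forward_backward(data, params)
            np.testing.assert_allclose(post.gamma, expect, atol=1e-10)
            # total log-likelihood equals log-sum over paths
            total = logps.max() + np.log(np.exp(logps - logps.max()).sum())
            np.testing.assert_allclose(ll, total, rtol=1e-10)

    def test_identical_emissions_give_chain_marginals(self):
        # when all states emit identically, gamma rows equal the Markov marginals
        rng = np.random.default_rng(5)
        K, T = 3, 6
        mean = rng.normal(size=3)
        means = np.tile(mean, (K, 1))
        covs = np.tile(np.eye(3), (K, 1, 1))
        trans = rng.dirichlet(np.ones(K), size=K)
        init = rng.dirichlet(np.ones(K))
        params = bs.HMMParameters(means, covs, trans, init)
        data = rng.normal(size=(T, 3))
        post, _, _ = bs.forward_backward(data, params)
        marg = init.copy()
        for t in range(T):
            np.testing.assert_allclose(post.gamma[t], marg, atol=1e-10)
            marg = marg @ trans

    def test_cross_check_against_hmmlearn(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(6)
        params, data = random_hmm_instance(rng, K=3, T=40, P=2)
        model = hmmlearn.GaussianHMM(n_components=3, covariance_type="full", init_params="")
        model.startprob_ = params.initial
        model.transmat_ = params.transition
        model.means_ = params.means
        model.covars_ = params.covariances
        post, _, ll = bs.forward_backward(data, params)
        ll_ref, gamma_ref = model.score_samples(data)
        np.testing.assert_allclose(ll, ll_ref, rtol=1e-8)
        np.testing.assert_allclose(post.gamma, gamma_ref, atol=1e-8)

    def test_posterior_rows_sum_to_one(self, four_state_fit):
        data, bounds, fit = four_state_fit
        post, xi, _ = bs.forward_backward(data[:500], fit, [0])
        np.testing.assert_allclose(post.gamma.sum(1), 1.0, atol=1e-8)
        # xi totals expected transitions: T-1 per run
        np.testing.assert_allclose(xi.sum(), 499, atol=1e-6)


class TestEMFit:
    def test_k1_recovers_gaussian_mle(self):
        rng = np.random.default_rng(7)
        mu = np.array([2.0, -1.0])
        data = rng.multivariate_normal(mu, np.eye(2), size=2000)
        fit = bs.em_fit(data, K=1, seed=8, max_iter=50)
        se = 1.0 / np.sqrt(2000)
        assert np.all(np.abs(fit.means[0] - mu) < 3 * se)

    def test_loglik_trace_monotone(self, four_state_fit):
        _, _, fit = four_state_fit
        trace = fit.log_likelihood_trace
        assert trace is not None and len(trace) >= 1
        assert np.all(np.diff(trace) >= -1e-6)

    def test_parameter_recovery_on_synthetic_group(self, four_state_group, four_state_fit):
        data, bounds, fit = four_state_fit
        true = np.concatenate([s.labels for s in four_state_group.truth.state_sequences])
        oracle_means = np.array([data[true == k].mean(0) for k in range(4)])
        perm = bs.match_states(fit.means, oracle_means)
        matched = bs.relabel(fit, perm)
        assert np.abs(matched.means - oracle_means).max() < 0.1
        assert np.abs(np.diag(matched.transition) - 0.9).max() < 0.05

    def test_transition_rows_and_initial_normalized(self, four_state_fit):
        _, _, fit = four_state_fit
        np.testing.assert_allclose(fit.transition.sum(1), 1.0, atol=1e-10)
        np.testing.assert_allclose(fit.initial.sum(), 1.0, atol=1e-10)


class TestRestarts:
    def test_single_restart_equals_em_fit(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(200, 3))
        direct_seed = int(np.random.default_rng(10).integers(2**31 - 1, size=1)[0])
        a = bs.fit_with_restarts(data, None, K=2, n_restarts=1, seed=10, max_iter=20)
        b = bs.em_fit(data, None, K=2, seed=direct_seed, max_iter=20)
        np.testing.assert_allclose(a.log_likelihood, b.log_likelihood)

    def test_returns_best_and_deterministic(self):
        rng = np.random.default_rng(11)
        data = rng.normal(size=(300, 2))
        data[:150] += 3
        a = bs.fit_with_restarts(data, None, K=2, n_restarts=3, seed=12, max_iter=30)
        b = bs.fit_with_restarts(data, None, K=2, n_restarts=3, seed=12, max_iter=30)
        np.testing.assert_array_equal(a.means, b.means)


class TestViterbi:
    def test_k1_all_zeros(self):
        rng = np.random.default_rng(13)
        data = rng.normal(size=(15, 2))
        params = bs.HMMParameters(
            data.mean(0)[None], (np.cov(data.T) + 1e-6 * np.eye(2))[None], [[1.0]], [1.0]
        )
        seq = bs.viterbi_decode(data, params)
        assert np.all(seq.labels == 0)

    @pytest.mark.parametrize("K,T", [(2, 5), (2, 8), (3, 5), (3, 7)])
    def test_matches_exhaustive_enumeration(self, K, T):
        rng = np.random.default_rng(100 + 10 * K + T)
        for _ in range(25):
            params, data = random_hmm_instance(rng, K=K, T=T)
            paths, logps = enumerate_paths(params, data)
            best = logps.max()
            seq = bs.viterbi_decode(data, params)
            np.testing.assert_allclose(
                path_logprob(params, data, tuple(seq.labels)), best, rtol=1e-10
            )

    def test_decoding_accuracy_on_separated_data(self, four_state_group, four_state_fit):
        data, bounds, fit = four_state_fit
        seq = bs.viterbi_decode(data, fit, bounds)
        true = np.concatenate([s.labels for s in four_state_group.truth.state_sequences])
        oracle_means = np.array([data[true == k].mean(0) for k in range(4)])
        perm = bs.match_states(fit.means, oracle_means)
        assert np.mean(perm[seq.labels] == true) >= 0.99

    def test_label_permutation_equivariance(self, four_state_fit):
        data, bounds, fit = four_state_fit
        perm = np.array([2, 0, 3, 1])
        seq = bs.viterbi_decode(data[:300], fit, [0])
        seq_p = bs.viterbi_decode(data[:300], bs.relabel(fit, perm), [0])
        np.testing.assert_array_equal(perm[seq.labels], seq_p.labels)


class TestCalinskiHarabasz:
    def test_zero_within_scatter_capped(self):
        data = np.array([[0.0], [0.0], [10.0], [10.0]])
        assert bs.calinski_harabasz(data, [0, 0, 1, 1]) == CH_CAP

    def test_hand_computed_value(self):
        data = np.array([[0.0], [2.0], [10.0], [12.0]])
        # trace(B)=100, trace(W)=4 → (100/1)/(4/2) = 50
        assert bs.calinski_harabasz(data, [0, 0, 1, 1]) == pytest.approx(50.0)

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            bs.calinski_harabasz(np.zeros((4, 2)), [1, 1, 1, 1])

    def test_cross_check_against_sklearn(self):
        from sklearn.metrics import calinski_harabasz_score

        rng = np.random.default_rng(14)
        data = rng.normal(size=(60, 4))
        labels = rng.integers(0, 3, size=60)
        assert bs.calinski_harabasz(data, labels) == pytest.approx(
            calinski_harabasz_score(data, labels), rel=1e-10
        )


class TestSelectK:
    def test_two_state_trivially_separated(self):
        params = bs.sample_hmm_params(2, 4, mean_separation=4, self_prob=0.9,
                                      cov_style="diagonal", seed=15)
        ds = bs.simulate_group(params, n_subjects=4, T=200, seed=16)
        K, scores = bs.select_K(ds.runs, candidate_Ks=[2, 3], seed=17, n_restarts=1)
        assert K == 2

    def test_requires_three_subjects(self, four_state_params):
        ds = bs.simulate_group(four_state_params, n_subjects=2, T=60, seed=18)
        with pytest.raises(ValueError):
            bs.select_K(ds.runs, candidate_Ks=[2], seed=19)


class TestSurrogates:
    def test_zero_shift_reproduces_real_fit(self, four_state_fit):
        data, bounds, _ = four_state_fit
        sub = data[:600]
        shifted = bs.circular_shift(sub, offsets=0)
        np.testing.assert_array_equal(shifted, sub)

    def test_marginal_multisets_preserved_and_covariance_destroyed(self, four_state_fit):
        data, bounds, fit = four_state_fit
        ens = bs.fit_surrogate_ensemble(
            data, bounds, K=4, n_iter=3, seed=20, max_em_iter=20, tol=1e-1
        )
        assert len(ens) == 3
        # covariance strength of surrogate states falls below the real fit's
        real = bs.covariance_strength(fit.covariances).mean()
        null = np.array([bs.covariance_strength(e.covariances).mean() for e in ens])
        assert np.all(null < real)

    def test_shift_conserves_column_values(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=(50, 4))
        y = bs.circular_shift(x, seed=22)
        for j in range(4):
            np.testing.assert_allclose(np.sort(x[:, j]), np.sort(y[:, j]))


class TestSerialization:
    def test_hmm_parameters_json_roundtrip(self, tmp_path, four_state_params):
        path = bs.save_hmm_parameters(four_state_params, tmp_path / "params.json")
        back = bs.load_hmm_parameters(path)
        np.testing.assert_allclose(back.means, four_state_params.means)
        np.testing.assert_allclose(back.covariances, four_state_params.covariances)
        np.testing.assert_allclose(back.transition, four_state_params.transition)
        back.validate()

    def test_state_sequence_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(30)
        seq = bs.StateSequence(rng.integers(0, 4, 120), K=4, run_boundary_index=[0, 50])
        path = bs.save_state_sequence(seq, tmp_path / "seq.tsv")
        back = bs.load_state_sequence(path)
        np.testing.assert_array_equal(back.labels, seq.labels)
        assert back.K == 4 and back.run_boundary_index == [0, 50]
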