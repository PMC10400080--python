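import numpy as np
import pytest

import brainstates as bs


@pytest.fixture(scope="session")
def four_state_params():
    """Well-separated 4-state generating model (P=10, full covariances)."""
    return bs.sample_hmm_params(
        K=4, P=10, mean_separation=3.0, self_prob=0.9, cov_style="random_full", seed=11
    )


@pytest.fixture(scope="session")
def four_state_group(four_state_params):
    """8-subject group simulated from the shared 4-state model (T=600 each)."""
    return bs.simulate_group(four_state_params, n_subjects=8, T=600, seed=12)


@pytest.fixture(scope="session")
def four_state_fit(four_state_group):
    """EM fit (3 restarts) on the z-normalized concatenated group data."""
    data, bounds = bs.concatenate_runs(
        [bs.znormalize(r) for r in four_state_group.runs]
    )
    fit = bs.fit_with_restarts(data, bounds, K=4, n_restarts=3, seed=13, max_iter=200)
    return data, bounds, fit


def random_hmm_instance(rng, K, T, P=2):
    """A small random Gaussian HMM instance + observations for oracle checks."""
    means = rng.normal(scale=2.0, size=(K, P))
    covs = np.array([np.eye(P) * rng.uniform(0.5, 2.0) for _ in range(K)])
    trans = rng.dirichlet(np.ones(K), size=K)
    init = rng.dirichlet(np.ones(K))
    params = bs.HMMParameters(means, covs, trans, init)
    data = rng.normal(size=(T, P))
    return params, data
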