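import logging

import numpy as np
import pytest

from semisoft.datasets import SyntheticConfig, make_ssl_split, simulate_batches
from semisoft.elm import init_nclelm
from semisoft.ensemble import Scaler
from semisoft.pseudolabel import build_plo_problem

logging.getLogger("semisoft").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_regression(rng):
    """A 30x3 nonlinear regression problem."""
    X = rng.normal(size=(30, 3))
    y = np.sin(X[:, 0]) + 0.5 * X[:, 1] * X[:, 2] + 0.05 * rng.normal(size=30)
    return X, y


def make_plo_problem(seed, n_labeled=25, u_prime=12, m=3, n_node=6, n_elm=3,
                     gammas=(0.5, 0.01, 0.5), noise_sd=0.05):
    """A small, well-conditioned pseudo-labeling problem on synthetic data."""
    table = simulate_batches(
        SyntheticConfig(n_batches=8, samples_per_batch=25, n_inputs=6,
                        noise_sd=noise_sd, rng_seed=seed)
    )
    data = make_ssl_split(table, n_labeled=n_labeled, n_val=10, rng_seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    rows = np.sort(rng.choice(data.X_u.shape[0], size=u_prime, replace=False))
    scaler = Scaler.fit(np.vstack([data.X_l, data.X_u]))
    X_l = scaler.transform(data.X_l)
    X_u = scaler.transform(data.X_u[rows])
    models = [
        init_nclelm(X_l.shape[1], n_node, n_elm, 0.6, seed + 50 + i) for i in range(m)
    ]
    problem = build_plo_problem(
        X_l, data.y_l, X_u, models, gammas, partition_seed=seed + 9
    )
    return problem, data.y_u_true[rows]


@pytest.fixture
def plo_problem():
    problem, _ = make_plo_problem(seed=7)
    return problem
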