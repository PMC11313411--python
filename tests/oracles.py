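"""Independent oracles used by the test-suite.

These deliberately avoid the package's forward recursion: the likelihood is
recomputed by brute-force enumeration over every latent state path, so a
test agreement is evidence that the dynamic-programming implementation is
right, not just self-consistent.
"""

from itertools import product

import numpy as np

from poolhmm.model import MonthlyHistory, ModelParams, build_transition, emission_table


def enumerate_loglik(
    history: MonthlyHistory, params: ModelParams, effort: np.ndarray
) -> float:
    """Log-likelihood by summing over all latent state paths.

    The initial state is the asserted release state (alive/operable in the
    release pool); the release-month observation contributes probability 1.
    Exponential in the history length: only usable for lengths of ~5-6.
    """
    P = params.n_pools
    S = P + 3
    T = build_transition(params)
    L = len(history.obs)
    if L == 1:
        return 0.0
    etabs = [
        emission_table(params, effort[:, history.release_month + k])
        for k in range(L)
    ]
    total = 0.0
    for path in product(range(S), repeat=L - 1):
        prev = history.release_pool
        p = 1.0
        for k, s in enumerate(path):
            p *= T[s, prev] * etabs[k + 1][history.obs[k + 1], s]
            if p == 0.0:
                break
            prev = s
        total += p
    if total <= 0.0:
        return -np.inf
    return float(np.log(total))


def random_params(
    rng: np.random.Generator, n_pools: int = 6, intercept: float = -5.0
) -> ModelParams:
    """A random valid parameter vector (Dirichlet columns, N(theta,sigma) betas)."""
    psi = rng.dirichlet(np.ones(n_pools), size=n_pools).T  # columns on the simplex
    theta = float(rng.normal(0.0, 1.0))
    sigma = float(rng.uniform(0.2, 2.0))
    return ModelParams(
        phi=float(rng.uniform(0.0, 1.0)),
        delta=float(rng.uniform(0.0, 1.0)),
        psi=psi,
        beta=rng.normal(theta, sigma, size=n_pools),
        theta=theta,
        sigma=sigma,
        intercept=intercept,
    )


def random_history(
    rng: np.random.Generator, n_pools: int = 6, max_len: int = 5
) -> MonthlyHistory:
    """A random observation sequence (not necessarily probable, but legal)."""
    L = int(rng.integers(2, max_len + 1))
    release_pool = int(rng.integers(0, n_pools))
    obs = np.empty(L, dtype=int)
    obs[0] = release_pool
    expired = False
    for k in range(1, L):
        if expired:
            obs[k] = n_pools + 1
        else:
            obs[k] = int(rng.integers(0, n_pools + 2))
            expired = obs[k] == n_pools + 1
    return MonthlyHistory(
        fish_id="x", release_month=0, release_pool=release_pool, obs=obs
    )
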