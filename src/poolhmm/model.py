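"""Multistate hidden-Markov model for monthly pool-to-pool fish movement.

The latent state of a tagged fish in month ``t`` combines its location with a
vital/technical status: alive with an operable transmitter battery in one of
``P`` river pools (``A/O`` pool 1..P), dead with an operable battery (``D/O``),
alive with an expired battery (``A/E``), or dead with an expired battery
(``D/E``).  Monthly dynamics are governed by

* ``phi``   -- probability of surviving the month,
* ``delta`` -- probability of the battery remaining operable, and
* ``psi``   -- a column-stochastic ``P x P`` matrix of pool transitions,
  ``psi[i, j]`` = probability of moving to pool ``i`` from pool ``j``
  conditional on staying alive with an operable battery.

The observation each month is one of: detected in pool ``j`` (only possible
for a live fish with an operable battery in pool ``j``), not detected, or
battery expired (asserted in the data from the projected expiration date
onward).  Detection in pool ``j`` in month ``t`` follows a logistic curve in
the receiver effort ``x[j, t]`` (mean receivers deployed per day):

    rho[j, t] = logistic(-5 + beta[j] * x[j, t])

with the intercept pinned at -5 so that detection probability approaches zero
as receiver coverage approaches zero.  The pool effects ``beta[j]`` are drawn
from a normal hyperdistribution ``N(theta, sigma)``.

The marginal likelihood of an observation sequence is computed by the scaled
forward recursion, summing over all latent state paths.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit, gammaln

__all__ = [
    "ModelParams",
    "MonthlyHistory",
    "PackedHistories",
    "state_labels",
    "detection_prob",
    "build_transition",
    "emission_dist",
    "emission_table",
    "forward_loglik",
    "batch_forward_loglik",
    "log_prior",
    "ParamTransform",
]

# Fixed logit intercept of the detection curve.
DETECTION_INTERCEPT = -5.0

# Observation symbol codes, for P pools:
#   0..P-1  detected in pool j
#   P       not detected
#   P+1     battery expired
#   P+2     padding sentinel (no observation; contributes likelihood 1)
SYM_NOT_DETECTED = "nd"
SYM_EXPIRED = "exp"
SYM_PAD = "pad"


def state_labels(n_pools: int) -> list[str]:
    return [f"A/O-{j + 1}" for j in range(n_pools)] + ["D/O", "A/E", "D/E"]


@dataclass
class ModelParams:
    """Full parameter vector of the movement HMM.

    ``psi`` is destination-by-origin: column ``j`` is the distribution over
    destination pools for a fish currently in pool ``j``.
    """

    phi: float
    delta: float
    psi: np.ndarray
    beta: np.ndarray
    theta: float = 0.0
    sigma: float = 1.0
    intercept: float = DETECTION_INTERCEPT

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))

    @property
    def n_pools(self) -> int:
        return self.psi.shape[0]

    def validate(self, atol: float = 1e-10) -> None:
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError(f"phi={self.phi} outside [0, 1]")
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError(f"delta={self.delta} outside [0, 1]")
        if self.sigma < 0:
            raise ValueError(f"sigma={self.sigma} must be non-negative")
        if self.psi.ndim != 2 or self.psi.shape[0] != self.psi.shape[1]:
            raise ValueError("psi must be a square matrix")
        if self.beta.shape != (self.n_pools,):
            raise ValueError("beta must have one entry per pool")
        if np.any(self.psi < -atol):
            raise ValueError("psi entries must be non-negative")
        colsums = self.psi.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=atol):
            raise ValueError(f"psi columns must sum to 1, got {colsums}")

    def copy(self) -> "ModelParams":
        return replace(self, psi=self.psi.copy(), beta=self.beta.copy())


def detection_prob(beta_j, x, intercept: float = DETECTION_INTERCEPT):
    """Monthly detection probability rho = logistic(intercept + beta * x).

    Vectorized over both arguments.  With the -5 intercept, zero effort gives
    rho = logistic(-5) ~= 0.0067 regardless of beta: pools with no receivers
    are nearly, but never exactly, undetectable.
    """
    return expit(intercept + np.asarray(beta_j) * np.asarray(x))


def build_transition(params: ModelParams) -> np.ndarray:
    """State-transition matrix, column = state at t, row = state at t+1.

    Layout (P pools): states ``0..P-1`` = A/O in pool, ``P`` = D/O,
    ``P+1`` = A/E, ``P+2`` = D/E.  From A/O in pool j a fish moves to A/O in
    pool i with ``phi*delta*psi[i, j]``, to D/O with ``(1-phi)*delta``, to
    A/E with ``phi*(1-delta)`` and to D/E with ``(1-phi)*(1-delta)``.  Dead
    fish cannot revive and expired batteries cannot recover; D/E is
    absorbing.  Every column sums to one.
    """
    params.validate()
    phi, delta, psi = params.phi, params.delta, params.psi
    P = params.n_pools
    S = P + 3
    T = np.zeros((S, S))
    T[:P, :P] = phi * delta * psi
    T[P, :P] = (1.0 - phi) * delta
    T[P + 1, :P] = phi * (1.0 - delta)
    T[P + 2, :P] = (1.0 - phi) * (1.0 - delta)
    T[P, P] = delta
    T[P + 2, P] = 1.0 - delta
    T[P + 1, P + 1] = phi
    T[P + 2, P + 1] = 1.0 - phi
    T[P + 2, P + 2] = 1.0
    return T


def emission_table(params: ModelParams, effort_t: np.ndarray) -> np.ndarray:
    """Emission probabilities for one month: array (P+3 symbols, P+3 states).

    Row ``s`` is the probability of each latent state emitting symbol ``s``
    given that month's per-pool effort.  The final row is the padding symbol
    (no observation), which every state "emits" with probability 1 so that
    padded months contribute a factor of one to the likelihood.
    """
    P = params.n_pools
    rho = detection_prob(params.beta, np.asarray(effort_t), params.intercept)
    E = np.zeros((P + 3, P + 3))
    for j in range(P):
        E[j, j] = rho[j]  # detected in pool j: only A/O-j
    E[P, :P] = 1.0 - rho  # not detected: undetected A/O
    E[P, P] = 1.0  # ... or D/O (dead fish are unobservable)
    E[P + 1, P + 1] = 1.0  # battery expired: A/E
    E[P + 1, P + 2] = 1.0  # ... or D/E
    E[P + 2, :] = 1.0  # padding
    return E


def emission_dist(state: int, effort_t: np.ndarray, params: ModelParams) -> np.ndarray:
    """Distribution over observation symbols for one latent state."""
    return emission_table(params, effort_t)[:, state][: params.n_pools + 2]


@dataclass
class MonthlyHistory:
    """One fish's monthly observation sequence.

    ``obs[k]`` is the symbol for month ``release_month + k`` (0-based month
    indices): ``0..P-1`` detected in that pool, ``P`` not detected, ``P+1``
    battery expired.  The first entry is the asserted release observation
    (detected in the release pool) and contributes probability one.
    """

    fish_id: str
    release_month: int
    release_pool: int  # 0-based
    obs: np.ndarray
    expire_month: int | None = None  # 0-based month of asserted expiry

    def __post_init__(self) -> None:
        self.obs = np.asarray(self.obs, dtype=int)
        if len(self.obs) == 0:
            raise ValueError(f"{self.fish_id}: empty observation sequence")


class PackedHistories:
    """Column-packed observation sequences for vectorized likelihoods.

    ``obs`` is (n_fish, n_months) of symbol codes with the padding code
    ``P+2`` outside each fish's active window.  Months after the first
    asserted-expired month are padded: once the chain is confined to the
    closed expired block, every later month contributes a factor of one, so
    dropping them changes nothing (verified in the test-suite).
    """

    def __init__(self, histories: list[MonthlyHistory], n_months: int, n_pools: int):
        self.n_pools = n_pools
        self.n_months = n_months
        self.fish_ids = [h.fish_id for h in histories]
        n = len(histories)
        pad = n_pools + 2
        self.release_month = np.array([h.release_month for h in histories], dtype=int)
        self.release_pool = np.array([h.release_pool for h in histories], dtype=int)
        self.obs = np.full((n, n_months), pad, dtype=int)
        for r, h in enumerate(histories):
            if h.release_month + len(h.obs) > n_months:
                raise ValueError(f"{h.fish_id}: history runs past month {n_months}")
            seq = h.obs.copy()
            expired = np.nonzero(seq == n_pools + 1)[0]
            if expired.size:  # truncate one month into the expired block
                seq = seq[: expired[0] + 1]
            self.obs[r, h.release_month : h.release_month + len(seq)] = seq

    def __len__(self) -> int:
        return self.obs.shape[0]


def batch_forward_loglik(
    packed: PackedHistories,
    params: ModelParams,
    effort: np.ndarray,
    per_fish: bool = False,
):
    """Marginal log-likelihood of all observation sequences.

    Scaled forward recursion over the P+3 latent states, vectorized across
    fish.  Initial condition: point mass on A/O in the release pool at the
    release month (the release observation is asserted, not modelled).
    Returns the total log-likelihood, or the per-fish vector.  An impossible
    observation yields -inf for that fish.
    """
    P = packed.n_pools
    if effort.shape != (P, packed.n_months):
        raise ValueError(
            f"effort must be (n_pools, n_months) = ({P}, {packed.n_months})"
        )
    n = len(packed)
    S = P + 3
    nT = packed.n_months
    T = build_transition(params)
    Tt = T.T.copy()

    # Emission tables for all months at once: Etab[t, symbol, state].
    rho = detection_prob(params.beta[:, None], effort, params.intercept)  # (P, nT)
    Etab = np.zeros((nT, S, S))
    tt = np.arange(nT)[:, None]
    jj = np.arange(P)[None, :]
    Etab[tt, jj, jj] = rho.T
    Etab[:, P, :P] = 1.0 - rho.T
    Etab[:, P, P] = 1.0
    Etab[:, P + 1, P + 1] = 1.0
    Etab[:, P + 1, P + 2] = 1.0
    Etab[:, P + 2, :] = 1.0
    # Per-fish emission rows, gathered once: (nT, n, S).
    E_sel = Etab[np.arange(nT)[:, None], packed.obs.T, :]

    ll = np.zeros(n)
    alpha = np.zeros((n, S))
    alpha[np.arange(n), packed.release_pool] = 1.0
    first = int(packed.release_month.min())
    # Fish only enter the recursion after their release month; before that
    # their alpha row sits untouched at the release point mass.
    for t in range(first + 1, nT):
        active = packed.release_month < t
        prop = (alpha @ Tt) * E_sel[t]
        c = prop.sum(axis=1)
        dead_end = active & (c <= 0.0)
        ok = active & (c > 0.0)
        if dead_end.any():
            ll[dead_end] = -np.inf
            alpha[dead_end] = 0.0
        ll[ok] += np.log(c[ok])
        np.divide(prop, np.where(c > 0.0, c, 1.0)[:, None], out=prop)
        alpha[ok] = prop[ok]
    return ll if per_fish else float(ll.sum())


def forward_loglik(
    history: MonthlyHistory, params: ModelParams, effort: np.ndarray
) -> float:
    """Marginal log-likelihood of a single history (see batch version)."""
    effort = np.asarray(effort, dtype=float)
    n_months = history.release_month + len(history.obs)
    packed = PackedHistories([history], n_months, params.n_pools)
    return float(
        batch_forward_loglik(packed, params, effort[:, :n_months], per_fish=True)[0]
    )


def log_prior(
    params: ModelParams,
    hierarchical: bool = True,
    dirichlet_alpha: float = 1.0,
    sigma_max: float = 5.0,
) -> float:
    """Joint log prior density of the model parameters.

    phi, delta ~ Uniform(0, 1); each psi column ~ Dirichlet(alpha, ..., alpha)
    (alpha = 1 is flat over the simplex); theta ~ N(0, 1);
    sigma ~ Uniform(0, sigma_max); beta[j] ~ N(theta, sigma).  With
    ``hierarchical=False`` (used by the collapsed single-pool cross-check)
    the beta prior is standard normal and theta/sigma drop out.
    """
    p = params
    if not (0.0 <= p.phi <= 1.0) or not (0.0 <= p.delta <= 1.0):
        return -np.inf
    if np.any(p.psi < 0.0) or not np.allclose(p.psi.sum(axis=0), 1.0, atol=1e-8):
        return -np.inf
    P = p.n_pools
    a = dirichlet_alpha
    lp = 0.0
    # Dirichlet(a,...,a) per column; alpha=1 reduces to log Gamma(P).
    with np.errstate(divide="ignore"):
        log_psi = np.log(p.psi)
    if a != 1.0 and np.any(np.isneginf(log_psi)):
        return -np.inf
    lp += P * (gammaln(P * a) - P * gammaln(a))
    if a != 1.0:
        lp += (a - 1.0) * log_psi.sum()
    if hierarchical:
        if not (0.0 < p.sigma < sigma_max):
            return -np.inf
        lp += -0.5 * p.theta**2 - 0.5 * np.log(2.0 * np.pi)  # theta ~ N(0,1)
        lp += -np.log(sigma_max)  # sigma ~ U(0, sigma_max)
        z = (p.beta - p.theta) / p.sigma
        lp += float(
            np.sum(-0.5 * z**2 - np.log(p.sigma) - 0.5 * np.log(2.0 * np.pi))
        )
    else:
        lp += float(np.sum(-0.5 * p.beta**2 - 0.5 * np.log(2.0 * np.pi)))
    return float(lp)


class ParamTransform:
    """Bijection between ModelParams and an unconstrained vector.

    Layout: [logit(phi), logit(delta), z_psi (P*(P-1)), beta (P), theta,
    logit(sigma/sigma_max)]; in the non-hierarchical variant theta and sigma
    are dropped.  psi columns use the additive log-ratio transform with the
    last pool as the anchor; its log-Jacobian is the sum of the log
    probabilities of all P components.
    """

    def __init__(
        self,
        n_pools: int,
        hierarchical: bool = True,
        sigma_max: float = 5.0,
        intercept: float = DETECTION_INTERCEPT,
    ):
        self.n_pools = n_pools
        self.hierarchical = hierarchical
        self.sigma_max = sigma_max
        self.intercept = intercept
        P = n_pools
        self.n_free_psi = P * (P - 1)
        self.dim = 2 + self.n_free_psi + P + (2 if hierarchical else 0)

    @staticmethod
    def _logit(p: float) -> float:
        p = min(max(p, 1e-12), 1.0 - 1e-12)
        return float(np.log(p / (1.0 - p)))

    def pack(self, params: ModelParams) -> np.ndarray:
        P = self.n_pools
        x = np.empty(self.dim)
        x[0] = self._logit(params.phi)
        x[1] = self._logit(params.delta)
        k = 2
        psi = np.clip(params.psi, 1e-12, None)
        for j in range(P):
            col = psi[:, j]
            x[k : k + P - 1] = np.log(col[:-1]) - np.log(col[-1])
            k += P - 1
        x[k : k + P] = params.beta
        k += P
        if self.hierarchical:
            x[k] = params.theta
            x[k + 1] = self._logit(params.sigma / self.sigma_max)
        return x

    def unpack(self, x: np.ndarray) -> tuple[ModelParams, float]:
        """Return (params, log |d constrained / d unconstrained|)."""
        P = self.n_pools
        phi = expit(x[0])
        delta = expit(x[1])
        logjac = float(
            np.log(phi) + np.log1p(-phi) + np.log(delta) + np.log1p(-delta)
        )
        k = 2
        psi = np.empty((P, P))
        for j in range(P):
            z = np.concatenate([x[k : k + P - 1], [0.0]])
            z -= z.max()
            w = np.exp(z)
            col = w / w.sum()
            psi[:, j] = col
            logjac += float(np.sum(np.log(np.clip(col, 1e-300, None))))
            k += P - 1
        beta = x[k : k + P].copy()
        k += P
        if self.hierarchical:
            theta = float(x[k])
            u = expit(x[k + 1])
            sigma = self.sigma_max * u
            logjac += float(np.log(self.sigma_max) + np.log(u) + np.log1p(-u))
        else:
            theta, sigma = 0.0, 1.0
        params = ModelParams(
            phi=float(phi),
            delta=float(delta),
            psi=psi,
            beta=beta,
            theta=theta,
            sigma=float(sigma),
            intercept=self.intercept,
        )
        return params, logjac


def make_log_posterior(
    packed: PackedHistories,
    effort: np.ndarray,
    transform: ParamTransform,
    dirichlet_alpha: float = 1.0,
):
    """Unnormalized log posterior density on the unconstrained scale."""

    def logpost(x: np.ndarray) -> float:
        params, logjac = transform.unpack(x)
        lp = log_prior(
            params,
            hierarchical=transform.hierarchical,
            dirichlet_alpha=dirichlet_alpha,
            sigma_max=transform.sigma_max,
        )
        if not np.isfinite(lp):
            return -np.inf
        ll = batch_forward_loglik(packed, params, effort)
        return lp + logjac + ll

    return logpost
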