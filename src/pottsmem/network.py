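"""Diluted Potts autoassociative network: Hebbian storage and retrieval.

Each of ``N`` Potts units carries a graded activity distribution over ``S``
active states plus a quiescent state (row-stochastic ``sigma[i, 0..S]``).
Patterns are stored in four-index couplings by a covariance (Hebbian) rule on
a randomly diluted directed graph with mean in-degree ``c_m``:

    J_ij^kl = 1/(c_m a (1 - a/S)) * sum_mu v(xi_i^mu, k) v(xi_j^mu, l),

with ``v(xi, k) = delta(xi, k) - a/S`` for active states k.  Retrieval runs
sequential Glauber-like sweeps at inverse temperature ``beta`` against a
firing threshold ``U``:

    sigma_ik = exp(beta h_ik) / (exp(beta U) + sum_l exp(beta h_il)).

The quiescent state is handled as a pseudo-state of constant weight
``exp(beta U)``; active-state fields carry no explicit ``-U`` term (the two
conventions differ by a common shift of all fields and give identical
dynamics).

Performance-critical kernels (coupling construction and sweeps) are
numba-compiled; everything is driven by explicit seeded generators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numba import njit

from .patterns import ParameterError, PatternSet

__all__ = [
    "NetworkParams",
    "Connectivity",
    "Couplings",
    "NetworkState",
    "RetrievalResult",
    "build_connectivity",
    "build_couplings",
    "update_state",
    "overlap",
    "parent_overlap",
    "all_overlaps",
    "energy",
    "cue_state",
    "cue_and_retrieve",
    "storage_capacity_simulation",
]


@dataclass(frozen=True)
class NetworkParams:
    """Network-side parameters: size, states, sparsity, dilution, threshold,
    inverse temperature."""

    N: int
    S: int
    a: float
    c_m: int
    U: float = 0.5
    beta: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.c_m <= self.N - 1):
            raise ParameterError(f"c_m must lie in [1, N-1], got {self.c_m}")
        if self.beta <= 0:
            raise ParameterError("beta must be positive")
        if not (0 < self.a < 1):
            raise ParameterError("a must lie in (0, 1)")

    @property
    def a_tilde(self) -> float:
        return self.a / self.S


@dataclass
class Connectivity:
    """Directed random dilution stored CSR-style over receivers.

    ``indices[indptr[i]:indptr[i+1]]`` lists the senders j with an edge
    j -> i.  Entries are i.i.d. Bernoulli(c_m / N) off the diagonal.
    """

    indptr: np.ndarray
    indices: np.ndarray
    N: int
    c_m: int

    @property
    def mean_degree(self) -> float:
        return self.indices.size / self.N

    def to_dense(self) -> np.ndarray:
        adj = np.zeros((self.N, self.N), dtype=np.int8)
        for i in range(self.N):
            adj[i, self.indices[self.indptr[i]:self.indptr[i + 1]]] = 1
        return adj


@dataclass
class Couplings:
    """Edge-sparse Hebbian tensor: J[e] is the S x S block of edge e."""

    J: np.ndarray  # (n_edges, S, S)
    conn: Connectivity
    S: int
    a: float
    p: int


@dataclass
class NetworkState:
    """Row-stochastic activity matrix sigma[i, k], k = 0 (quiescent) .. S."""

    sigma: np.ndarray

    def validate(self) -> None:
        if np.any(self.sigma < 0) or not np.allclose(self.sigma.sum(axis=1), 1.0):
            raise ValueError("sigma rows must be nonnegative and sum to 1")


@dataclass
class RetrievalResult:
    m_cue: float
    m_corr: float
    m_fact: float
    sweeps: int
    converged: bool
    state: NetworkState = field(repr=False, default=None)


def build_connectivity(params: NetworkParams, seed: int | None = None) -> Connectivity:
    """Random dilution: each directed edge present independently w.p. c_m/N."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    prob = params.c_m / params.N
    indptr = np.zeros(params.N + 1, dtype=np.int64)
    rows = []
    for i in range(params.N):
        mask = rng.random(params.N) < prob
        mask[i] = False
        senders = np.flatnonzero(mask)
        rows.append(senders)
        indptr[i + 1] = indptr[i] + senders.size
    indices = np.concatenate(rows).astype(np.int64)
    return Connectivity(indptr=indptr, indices=indices, N=params.N, c_m=params.c_m)


@njit(cache=True)
def _build_J(indptr, indices, xi, S, a_tilde, norm):  # pragma: no cover
    N, p = xi.shape
    counts = np.zeros((N, S), dtype=np.int64)
    for i in range(N):
        for mu in range(p):
            k = xi[i, mu]
            if k > 0:
                counts[i, k - 1] += 1
    n_edges = indices.size
    J = np.zeros((n_edges, S, S))
    M = np.zeros((S, S), dtype=np.int64)
    for i in range(N):
        for e in range(indptr[i], indptr[i + 1]):
            j = indices[e]
            M[:, :] = 0
            for mu in range(p):
                k = xi[i, mu]
                l = xi[j, mu]
                if k > 0 and l > 0:
                    M[k - 1, l - 1] += 1
            for k in range(S):
                for l in range(S):
                    J[e, k, l] = (
                        M[k, l]
                        - a_tilde * counts[i, k]
                        - a_tilde * counts[j, l]
                        + p * a_tilde * a_tilde
                    ) * norm
    return J


def build_couplings(
    patterns: PatternSet, conn: Connectivity, params: NetworkParams
) -> Couplings:
    """Hebbian covariance rule summed over all stored patterns, on existing
    edges only."""
    if patterns.N != params.N or patterns.S != params.S:
        raise ValueError("pattern set does not match network shape")
    norm = 1.0 / (params.c_m * params.a * (1.0 - params.a_tilde))
    xi = np.ascontiguousarray(patterns.xi, dtype=np.int32)
    J = _build_J(conn.indptr, conn.indices, xi, params.S, params.a_tilde, norm)
    return Couplings(J=J, conn=conn, S=params.S, a=params.a, p=patterns.p)


@njit(cache=True)
def _sweep(indptr, indices, J, sigma, order, beta, U):  # pragma: no cover
    S = J.shape[1]
    maxdiff = 0.0
    h = np.empty(S)
    w = np.empty(S + 1)
    for idx in range(order.size):
        i = order[idx]
        for k in range(S):
            h[k] = 0.0
        for e in range(indptr[i], indptr[i + 1]):
            j = indices[e]
            for l in range(S):
                s = sigma[j, l + 1]
                if s > 0.0:
                    for k in range(S):
                        h[k] += J[e, k, l] * s
        # Boltzmann update with quiescent pseudo-state of weight exp(beta*U);
        # max-subtraction keeps the exponentials finite (results invariant to
        # common shifts of the fields)
        mx = U
        for k in range(S):
            if h[k] > mx:
                mx = h[k]
        z = math.exp(beta * (U - mx))
        w[0] = z
        for k in range(S):
            w[k + 1] = math.exp(beta * (h[k] - mx))
            z += w[k + 1]
        for k in range(S + 1):
            new = w[k] / z
            d = abs(new - sigma[i, k])
            if d > maxdiff:
                maxdiff = d
            sigma[i, k] = new
    return maxdiff


def update_state(
    state: NetworkState,
    couplings: Couplings,
    params: NetworkParams,
    order: np.ndarray,
) -> float:
    """One full sequential sweep in the given unit order (in place).

    Returns the maximum per-unit activity change of the sweep.
    """
    return _sweep(
        couplings.conn.indptr,
        couplings.conn.indices,
        couplings.J,
        state.sigma,
        np.asarray(order, dtype=np.int64),
        params.beta,
        params.U,
    )


def overlap(state: NetworkState, xi_col: np.ndarray, a: float, S: int) -> float:
    """Global overlap m = 1/(N a (1-a/S)) sum_i sum_k v(xi_i, k) sigma_ik."""
    sigma = state.sigma
    N = sigma.shape[0]
    a_tilde = a / S
    act = np.flatnonzero(xi_col > 0)
    term1 = sigma[act, xi_col[act]].sum()
    term2 = a_tilde * sigma[:, 1:].sum()
    return float((term1 - term2) / (N * a * (1.0 - a_tilde)))


def parent_overlap(state: NetworkState, parent_states: np.ndarray, S: int) -> float:
    """Overlap with a non-sparse parent (its own sparsity a=1, a~=1/S).

    Undefined for S=1 (a non-sparse binary parent is the all-active pattern,
    which has zero variance); returns 0 in that case.
    """
    if S == 1:
        return 0.0
    sigma = state.sigma
    N = sigma.shape[0]
    term1 = sigma[np.arange(N), parent_states].sum()
    term2 = sigma[:, 1:].sum() / S
    return float((term1 - term2) / (N * (1.0 - 1.0 / S)))


def all_overlaps(state: NetworkState, patterns: PatternSet) -> np.ndarray:
    """Overlaps of the state with every stored pattern (vectorized)."""
    sigma = state.sigma
    xi = patterns.xi
    a, S = patterns.a, patterns.S
    a_tilde = a / S
    gathered = np.take_along_axis(sigma, xi, axis=1)  # sigma[i, xi[i, mu]]
    gathered = np.where(xi > 0, gathered, 0.0)
    term2 = a_tilde * sigma[:, 1:].sum()
    return (gathered.sum(axis=0) - term2) / (patterns.N * a * (1.0 - a_tilde))


def energy(state: NetworkState, couplings: Couplings, params: NetworkParams) -> float:
    """Potts energy -1/2 sum J sigma sigma + U sum_{k>=1} sigma (diagnostic;
    a Lyapunov function only for symmetric connectivity)."""
    sigma = state.sigma
    conn = couplings.conn
    e_int = 0.0
    for i in range(conn.N):
        lo, hi = conn.indptr[i], conn.indptr[i + 1]
        js = conn.indices[lo:hi]
        # h_i,k = sum_j sum_l J[e,k,l] sigma[j,l]
        h = np.einsum("ekl,el->k", couplings.J[lo:hi], sigma[js, 1:])
        e_int += float(h @ sigma[i, 1:])
    return -0.5 * e_int + params.U * float(sigma[:, 1:].sum())


def cue_state(xi_col: np.ndarray, S: int, cue_fraction: float = 1.0,
              rng: np.random.Generator | None = None) -> NetworkState:
    """One-hot network state for a cue pattern.

    ``cue_fraction < 1`` resets a random complement of units to the uniform
    distribution over the S+1 states (partial cue).
    """
    N = xi_col.size
    sigma = np.zeros((N, S + 1))
    sigma[np.arange(N), xi_col] = 1.0
    if cue_fraction < 1.0:
        rng = np.random.default_rng(0) if rng is None else rng
        n_reset = int(round((1.0 - cue_fraction) * N))
        reset = rng.choice(N, size=n_reset, replace=False)
        sigma[reset] = 1.0 / (S + 1)
    return NetworkState(sigma=sigma)


def cue_and_retrieve(
    couplings: Couplings,
    patterns: PatternSet,
    cue_index: int,
    params: NetworkParams,
    tol: float = 1e-6,
    max_sweeps: int = 100,
    cue_fraction: float = 1.0,
    rng: np.random.Generator | None = None,
    keep_state: bool = False,
) -> RetrievalResult:
    """Cue one stored pattern and run sweeps to (approximate) convergence.

    Returns the overlap with the cue (``m_cue``), the best overlap among the
    other stored patterns (``m_corr``) and the best overlap among the parents
    (``m_fact``, 0 if the pattern set has no parents).
    """
    if not (0 <= cue_index < patterns.p):
        raise ValueError("cue index out of range")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    xi_cue = patterns.xi[:, cue_index]
    state = cue_state(xi_cue, params.S, cue_fraction, rng)
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        order = rng.permutation(params.N)
        maxdiff = update_state(state, couplings, params, order)
        if maxdiff < tol:
            converged = True
            break
    m_all = all_overlaps(state, patterns)
    m_cue = float(m_all[cue_index])
    others = np.delete(m_all, cue_index)
    m_corr = float(others.max()) if others.size else 0.0
    m_fact = 0.0
    if patterns.parents is not None:
        m_fact = max(
            parent_overlap(state, ps, params.S) for ps in patterns.parents.states
        )
    return RetrievalResult(
        m_cue=m_cue,
        m_corr=m_corr,
        m_fact=m_fact,
        sweeps=sweeps,
        converged=converged,
        state=state if keep_state else None,
    )


def _criterion_met(
    patterns: PatternSet,
    params: NetworkParams,
    n_cues: int,
    overlap_threshold: float,
    fraction: float,
    seed: int,
    tol: float,
    max_sweeps: int,
) -> float:
    rng = np.random.default_rng(seed)
    conn = build_connectivity(params, seed=seed + 1)
    coup = build_couplings(patterns, conn, params)
    cues = rng.choice(patterns.p, size=min(n_cues, patterns.p), replace=False)
    good = 0
    for c in cues:
        res = cue_and_retrieve(
            coup, patterns, int(c), params, tol=tol, max_sweeps=max_sweeps, rng=rng
        )
        if res.m_cue >= overlap_threshold:
            good += 1
    return good / cues.size


def storage_capacity_simulation(
    pattern_source: Callable[[int], PatternSet],
    params: NetworkParams,
    n_cues: int = 50,
    overlap_threshold: float = 0.7,
    fraction: float = 0.5,
    p_start: int | None = None,
    p_max: int | None = None,
    p_min: int = 1,
    seed: int = 0,
    tol: float = 1e-6,
    max_sweeps: int = 100,
    resolution: float = 0.02,
) -> float:
    """Simulated storage capacity alpha_c = p* / c_m.

    p* is the largest pattern count at which at least ``fraction`` of
    ``n_cues`` cued patterns are retrieved with overlap >= ``overlap_threshold``
    (fresh connectivity and couplings at every probed p; fixed
    pattern-generation seed policy via ``pattern_source``).  Grows p
    geometrically until the criterion first fails, then bisects down to a
    resolution of max(1, p/50).
    """

    def ok(p: int) -> bool:
        pats = pattern_source(p)
        frac = _criterion_met(
            pats, params, n_cues, overlap_threshold, fraction, seed, tol, max_sweeps
        )
        return frac >= fraction

    p = max(p_min, p_start or max(2, params.c_m // 10))
    cap = p_max or 50 * params.c_m
    if not ok(p):
        hi = p
        if p == p_min or not ok(p_min):
            import warnings

            warnings.warn(
                f"retrieval criterion not met even at p={p_min}", stacklevel=2
            )
            return 0.0
        lo = p_min
    else:
        while True:
            nxt = min(cap, int(math.ceil(p * 1.6)))
            if nxt == p or not ok(nxt):
                lo, hi = p, nxt
                break
            p = nxt
            if p >= cap:
                return p / params.c_m
    while hi - lo > max(1, int(resolution * lo)):
        mid = (lo + hi) // 2
        if ok(mid):
            lo = mid
        else:
            hi = mid
    return lo / params.c_m
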