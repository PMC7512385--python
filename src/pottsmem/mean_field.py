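"""Self-consistent signal-to-noise (mean-field) capacity of the Potts network.

In the mean-field closure, the crosstalk from non-condensed patterns acting on
a unit is split into a self-interaction term and Gaussian noise whose
amplitudes are fixed self-consistently.  At zero temperature a unit adopts the
state with the largest mean field

    H_k = v(xi, k) m + (alpha d / 2S) Psi - U + sum_n v(n, k) z_n rho_n,
    H_0 = 0,

with z_n standard normal, Psi = Omega/(1 - Omega), d = c_m/N, and per-state
noise amplitudes

    rho_n^2 = (alpha P_n / S) (1 - a~) q
              * [1 + 2 d Psi + d Psi^2]
              * [1 + (p C~/(a (1 - a~))) (C~ - a~)],

where P_n is the pattern-state marginal (1-a for n=0, a/S otherwise) and
C~ = mean pattern correlation: the second bracket is the correlation
correction, equal to 1 for uncorrelated patterns (C~ = a/S).  The order
parameters (m, q, Omega) satisfy fixed-point equations whose Gaussian and
pattern averages are evaluated here by seeded Monte-Carlo with common random
numbers across iterations; the storage capacity is the largest loading alpha
at which a solution with a finite condensed overlap m persists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .patterns import ParameterError

__all__ = [
    "OrderParams",
    "NoSolution",
    "mean_field_H",
    "solve_self_consistent",
    "capacity_from_scsna",
]


@dataclass
class OrderParams:
    """SCSNA order parameters at loading alpha."""

    m: float
    q: float
    Omega: float
    alpha: float
    a: float
    S: int
    dilution: float  # c_m / N
    c_m: int
    cas_bar: float
    U: float
    converged: bool = True
    residual: float = float("nan")

    @property
    def Psi(self) -> float:
        if self.Omega >= 1.0:
            raise NoSolution("Omega >= 1: divergent response")
        return self.Omega / (1.0 - self.Omega)

    @property
    def a_tilde(self) -> float:
        return self.a / self.S

    @property
    def correlation_correction(self) -> float:
        """1 + (p C~ / (a(1-a~))) (C~ - a~); 1 when patterns are uncorrelated."""
        p = self.alpha * self.c_m
        return 1.0 + p * self.cas_bar / (self.a * (1.0 - self.a_tilde)) * (
            self.cas_bar - self.a_tilde
        )

    def rho(self) -> np.ndarray:
        """Noise amplitude per state n = 0..S."""
        P = np.full(self.S + 1, self.a_tilde)
        P[0] = 1.0 - self.a
        B = 1.0 + 2.0 * self.dilution * self.Psi + self.dilution * self.Psi**2
        C = self.correlation_correction
        var = self.alpha * P / self.S * (1.0 - self.a_tilde) * self.q * B * C
        if np.any(var < 0):
            raise NoSolution("negative noise variance (correction overflow)")
        return np.sqrt(var)


class NoSolution(RuntimeError):
    """No finite-overlap fixed point at this loading."""


def _v(n: np.ndarray, k: int, a_tilde: float) -> np.ndarray:
    """Pattern operator v(n, k) = delta(n,k) - a~ (1 - delta(k,0))."""
    if k == 0:
        return (n == 0).astype(float)
    return (n == k).astype(float) - a_tilde


def mean_field_H(op: OrderParams, z: np.ndarray, xi: np.ndarray) -> np.ndarray:
    """Per-state mean fields H_k for given Gaussian draws and pattern states.

    ``z``: (..., S+1) standard normal deviates; ``xi``: (...,) pattern states.
    Returns an array with one more trailing axis of size S+1 (k = 0..S).
    """
    S = op.S
    a_tilde = op.a_tilde
    rho = op.rho()
    zr = z * rho  # (..., S+1)
    zr_sum = zr.sum(axis=-1)
    self_term = op.alpha * op.dilution * op.Psi / (2.0 * S)
    H = np.empty(z.shape)
    # the quiescent state receives no couplings (the Hebbian rule carries
    # (1 - delta_k0) factors), so its field is identically zero; its weight
    # is the threshold U, already subtracted from the active-state fields
    H[..., 0] = 0.0
    for k in range(1, S + 1):
        signal = ((xi == k).astype(float) - a_tilde) * op.m
        noise = zr[..., k] - a_tilde * zr_sum
        H[..., k] = signal + self_term - op.U + noise
    return H


def _draws(a: float, S: int, n_samples: int, seed: int):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, S + 1))
    u = rng.random(n_samples)
    xi = np.zeros(n_samples, dtype=np.int64)
    active = u < a
    xi[active] = rng.integers(1, S + 1, size=int(active.sum()))
    return z, xi


def solve_self_consistent(
    a: float,
    S: int,
    dilution: float,
    alpha: float,
    cas_bar: float | None = None,
    U: float = 0.5,
    c_m: int = 200,
    n_samples: int = 200_000,
    seed: int = 0,
    damping: float = 0.5,
    max_iter: int = 200,
    tol: float = 2e-3,
    m_min: float = 0.3,
) -> OrderParams:
    """Damped fixed-point iteration for (m, q, Omega) at loading alpha.

    The zero-temperature averages (each unit adopts the argmax state of its
    mean field; ties broken toward the lower state index) are evaluated over
    ``n_samples`` joint (z, xi) Monte-Carlo draws held fixed across iterations
    (common random numbers).  ``cas_bar`` defaults to the uncorrelated value
    a/S.  Raises :class:`NoSolution` when the iteration collapses to m < m_min,
    oscillates after one damping increase, or drives Omega to 1.
    """
    if not (0 < a < 1) or S < 1 or not (0 < dilution <= 1) or alpha <= 0:
        raise ParameterError("invalid mean-field parameters")
    a_tilde = a / S
    if cas_bar is None:
        cas_bar = a_tilde
    z, xi = _draws(a, S, n_samples, seed)
    P = np.full(S + 1, a_tilde)
    P[0] = 1.0 - a

    op = OrderParams(
        m=1.0, q=1.0, Omega=0.0, alpha=alpha, a=a, S=S, dilution=dilution,
        c_m=c_m, cas_bar=cas_bar, U=U,
    )
    lam = damping
    damp_raised = False
    prev_res = np.inf
    norm_m = a * (1.0 - a_tilde)
    for _ in range(max_iter):
        try:
            H = mean_field_H(op, z, xi)
        except NoSolution:
            raise
        winner = np.argmax(H, axis=-1)  # argmax breaks ties toward lower index
        active = winner > 0
        v_win = np.where(
            active, (xi == winner).astype(float) - a_tilde, 0.0
        )
        m_new = float(v_win.mean() / norm_m)
        q_new = float(active.mean() / a)
        # response parameter via the z-weighted average of the winner
        # indicator, with coefficient alpha q B C P_k/(S(1-a~)) per channel
        B = 1.0 + 2.0 * dilution * op.Psi + dilution * op.Psi**2
        C = op.correlation_correction
        coef = alpha * op.q * B * C * P / (S * (1.0 - a_tilde))
        # sum_k coef_k v(k, winner) z_k for active winners:
        # = coef_w z_w - a~ sum_k coef_k z_k
        cz = z @ coef
        z_w = np.take_along_axis(z, winner[:, None], axis=1)[:, 0]
        coef_w = coef[winner]
        contrib = np.where(active, coef_w * z_w - a_tilde * cz, 0.0)
        Omega_new = float(contrib.mean() / a_tilde)
        Omega_new = min(max(Omega_new, 0.0), 0.995)

        res = max(abs(m_new - op.m), abs(q_new - op.q), abs(Omega_new - op.Omega))
        op.m = (1 - lam) * op.m + lam * m_new
        op.q = (1 - lam) * op.q + lam * q_new
        op.Omega = (1 - lam) * op.Omega + lam * Omega_new
        if op.m < m_min:
            raise NoSolution(f"overlap collapsed (m={op.m:.3f}) at alpha={alpha}")
        if res < tol:
            op.converged = True
            op.residual = res
            return op
        if res > 2.0 * prev_res and not damp_raised:
            lam *= 0.4
            damp_raised = True
        prev_res = res
    raise NoSolution(f"no convergence after {max_iter} iterations at alpha={alpha}")


def capacity_from_scsna(
    a: float,
    S: int,
    dilution: float,
    cas_bar: float | None = None,
    U: float = 0.5,
    c_m: int = 200,
    alpha_tol: float = 1e-2,
    alpha_start: float = 0.5,
    n_samples: int = 200_000,
    seed: int = 0,
    **solver_kwargs,
) -> float:
    """Mean-field storage capacity: bisection on alpha between a solvable and
    an unsolvable loading, to a tolerance of ``alpha_tol``."""

    def solvable(alpha: float) -> bool:
        try:
            solve_self_consistent(
                a, S, dilution, alpha, cas_bar=cas_bar, U=U, c_m=c_m,
                n_samples=n_samples, seed=seed, **solver_kwargs,
            )
            return True
        except NoSolution:
            return False

    lo = alpha_start
    while not solvable(lo):
        lo /= 2.0
        if lo < 1e-3:
            raise ParameterError("no mean-field solution even at alpha ~ 0")
    hi = lo * 1.5
    while solvable(hi):
        lo = hi
        hi *= 1.5
        if hi > 1e3:  # pragma: no cover - guard
            return lo
    while hi - lo > alpha_tol:
        mid = 0.5 * (lo + hi)
        if solvable(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
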