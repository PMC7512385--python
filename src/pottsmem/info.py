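"""Mutual information between a cued pattern and the retrieved state.

The central quantity is the per-unit mutual information

    I(c, r) = sum_{k,l} C_kl log2[ C_kl / (C_k C_l) ],

where ``C_kl = (1/N) sum_i delta(xi_i^c, k) sigma_i^l`` is the joint
state-occupancy of the cued pattern c and the (graded) final network state r,
and C_k, C_l its marginals.  Its maximum over final states is the entropy of
the stored pattern, ``-(1-a) log2(1-a) + a log2(S/a)``, attained when the cue
itself is retrieved.

Above the storage capacity, retrieval of the detailed pattern fails, but for
intermediate values of the dominance rate zeta the network still settles into
a state carrying information about the cue (it retrieves the dominant
feature).  The *residual information* quantifies this: the mean mutual
information per connection over loadings in a window past the capacity
collapse.  Scanned over (zeta, f), it maps the phase where gross semantic
information survives even though individual memories are lost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .network import (
    NetworkParams,
    NetworkState,
    build_connectivity,
    build_couplings,
    cue_and_retrieve,
)
from .patterns import PatternSet

__all__ = [
    "pattern_entropy",
    "mutual_information",
    "InfoCurve",
    "info_vs_loading",
    "ResidualInfo",
    "residual_information",
    "measure_residual_information",
    "phase_diagram",
    "cluster_patterns",
]


def pattern_entropy(a: float, S: int) -> float:
    """Entropy (bits/unit) of a sparse Potts pattern: -(1-a)log2(1-a) + a log2(S/a)."""
    if not (0.0 <= a <= 1.0):
        raise ValueError(f"a must lie in [0, 1], got {a}")
    out = 0.0
    if a < 1.0:
        out -= (1.0 - a) * np.log2(1.0 - a)
    if a > 0.0:
        out += a * np.log2(S / a)
    return float(out)


def mutual_information(xi_col: np.ndarray, state: NetworkState) -> float:
    """Per-unit mutual information (bits) between pattern and graded state."""
    sigma = state.sigma
    N, S1 = sigma.shape
    C = np.zeros((S1, S1))
    for k in range(S1):
        sel = xi_col == k
        if sel.any():
            C[k] = sigma[sel].sum(axis=0)
    C /= N
    Ck = C.sum(axis=1, keepdims=True)
    Cl = C.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(C > 0, C / (Ck * Cl), 1.0)
        terms = np.where(C > 0, C * np.log2(ratio), 0.0)
    return float(terms.sum())


@dataclass
class InfoCurve:
    """Mean retrieval information and overlaps along a loading grid."""

    alphas: np.ndarray
    p_values: np.ndarray
    info_per_unit: np.ndarray
    info_per_connection: np.ndarray
    m_cue: np.ndarray
    m_corr: np.ndarray
    m_fact: np.ndarray
    shuffle_info: np.ndarray  # negative control: unit-permuted pairing
    n_cues: int
    c_m: int
    seed: int


def _mean_info_at_p(
    gen_factory: Callable[[int], PatternSet],
    params: NetworkParams,
    p: int,
    n_cues: int,
    seed: int,
    tol: float,
    max_sweeps: int,
) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    patterns = gen_factory(p)
    conn = build_connectivity(params, seed=seed + 1)
    coup = build_couplings(patterns, conn, params)
    cues = rng.choice(patterns.p, size=min(n_cues, patterns.p), replace=False)
    info, shuf, mc, mo, mf = [], [], [], [], []
    for c in cues:
        res = cue_and_retrieve(
            coup, patterns, int(c), params, tol=tol, max_sweeps=max_sweeps,
            rng=rng, keep_state=True,
        )
        xi_c = patterns.xi[:, int(c)]
        info.append(mutual_information(xi_c, res.state))
        perm = rng.permutation(params.N)
        shuf.append(mutual_information(xi_c[perm], res.state))
        mc.append(res.m_cue)
        mo.append(res.m_corr)
        mf.append(res.m_fact)
    return {
        "info": float(np.mean(info)),
        "shuffle": float(np.mean(shuf)),
        "m_cue": float(np.mean(mc)),
        "m_corr": float(np.mean(mo)),
        "m_fact": float(np.mean(mf)),
    }


def info_vs_loading(
    gen_factory: Callable[[int], PatternSet],
    params: NetworkParams,
    alphas: Sequence[float],
    n_cues: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_sweeps: int = 100,
) -> InfoCurve:
    """Evaluate mean cue-retrieval information on a grid of loadings.

    For each alpha, ``p = round(alpha * c_m)`` patterns are generated, a fresh
    network is built and ``n_cues`` patterns are cued; the per-unit mutual
    information of the final states is averaged.
    """
    alphas = np.asarray(list(alphas), dtype=float)
    rows = []
    p_values = []
    for j, alpha in enumerate(alphas):
        p = max(1, int(round(alpha * params.c_m)))
        p_values.append(p)
        rows.append(
            _mean_info_at_p(gen_factory, params, p, n_cues, seed + 7 * j, tol, max_sweeps)
        )
    info = np.array([r["info"] for r in rows])
    return InfoCurve(
        alphas=alphas,
        p_values=np.array(p_values),
        info_per_unit=info,
        info_per_connection=info / params.c_m,
        m_cue=np.array([r["m_cue"] for r in rows]),
        m_corr=np.array([r["m_corr"] for r in rows]),
        m_fact=np.array([r["m_fact"] for r in rows]),
        shuffle_info=np.array([r["shuffle"] for r in rows]),
        n_cues=n_cues,
        c_m=params.c_m,
        seed=seed,
    )


@dataclass
class ResidualInfo:
    """Post-collapse information plateau.

    ``per_unit``/``per_connection`` are bias-corrected by subtracting the
    shuffle (unit-permuted) control, which measures the finite-sampling bias
    of the plug-in mutual-information estimator (~(S)^2/(2N ln2) bits);
    ``raw_per_unit`` and ``bias_per_unit`` keep the uncorrected pieces.
    """

    per_connection: float
    per_unit: float
    raw_per_unit: float
    bias_per_unit: float
    alpha_collapse: float
    window: tuple[float, float]
    n_points: int


COLLAPSE_THRESHOLD = 0.35  # half the 0.7 retrieval criterion
WINDOW = (1.5, 2.5)  # post-collapse window in units of alpha_collapse


def residual_information(
    curve: InfoCurve,
    collapse_threshold: float = COLLAPSE_THRESHOLD,
    window: tuple[float, float] = WINDOW,
) -> ResidualInfo:
    """Mean information per connection over the post-collapse window.

    The collapse loading is the first grid point where the mean cue overlap
    drops below ``collapse_threshold``; the residual information averages
    I/c_m over grid points with alpha in ``window * alpha_collapse``.
    """
    below = np.flatnonzero(curve.m_cue < collapse_threshold)
    if below.size == 0:
        raise ValueError("capacity collapse not reached within the loading grid")
    alpha_c = float(curve.alphas[below[0]])
    lo, hi = window[0] * alpha_c, window[1] * alpha_c
    sel = (curve.alphas >= lo) & (curve.alphas <= hi)
    if not sel.any():
        raise ValueError("loading grid has no points in the post-collapse window")
    raw = float(curve.info_per_unit[sel].mean())
    bias = float(curve.shuffle_info[sel].mean())
    per_unit = raw - bias
    return ResidualInfo(
        per_connection=per_unit / curve.c_m,
        per_unit=per_unit,
        raw_per_unit=raw,
        bias_per_unit=bias,
        alpha_collapse=alpha_c,
        window=(lo, hi),
        n_points=int(sel.sum()),
    )


def measure_residual_information(
    gen_factory: Callable[[int], PatternSet],
    params: NetworkParams,
    n_cues: int = 20,
    n_window_points: int = 3,
    n_cues_search: int = 8,
    seed: int = 0,
    p_floor: int = 20,
    p_cap_factor: float = 40.0,
    tol: float = 1e-6,
    max_sweeps: int = 100,
    collapse_threshold: float = COLLAPSE_THRESHOLD,
    window: tuple[float, float] = WINDOW,
) -> ResidualInfo:
    """Locate the capacity collapse adaptively, then average the information
    over loadings in the post-collapse window.

    The collapse loading (mean cue overlap first below ``collapse_threshold``)
    is bracketed by geometric growth of p with a small cue sample, refined by
    bisection; the residual information is then measured with ``n_cues`` cues
    at ``n_window_points`` loadings spanning ``window * alpha_collapse``.
    """

    def mean_mcue(p: int, probe_seed: int) -> float:
        r = _mean_info_at_p(
            gen_factory, params, p, n_cues_search, probe_seed, tol, max_sweeps
        )
        return r["m_cue"]

    p = max(p_floor, params.c_m // 4)
    p_cap = int(p_cap_factor * params.c_m)
    if mean_mcue(p, seed + 1) < collapse_threshold:
        lo, hi = p_floor, p
    else:
        lo = p
        hi = None
        while p < p_cap:
            p = int(np.ceil(p * 1.5))
            if mean_mcue(p, seed + 1 + p % 97) < collapse_threshold:
                hi = p
                break
            lo = p
        if hi is None:
            raise ValueError("no capacity collapse below the loading cap")
    while hi - lo > max(2, int(0.12 * lo)):
        mid = (lo + hi) // 2
        if mean_mcue(mid, seed + 2 + mid % 89) < collapse_threshold:
            hi = mid
        else:
            lo = mid
    alpha_collapse = hi / params.c_m

    ws = np.linspace(window[0], window[1], n_window_points)
    infos, biases = [], []
    for j, w in enumerate(ws):
        p_w = int(round(w * alpha_collapse * params.c_m))
        r = _mean_info_at_p(
            gen_factory, params, p_w, n_cues, seed + 11 + 13 * j, tol, max_sweeps
        )
        infos.append(r["info"])
        biases.append(r["shuffle"])
    raw = float(np.mean(infos))
    bias = float(np.mean(biases))
    per_unit = raw - bias
    return ResidualInfo(
        per_connection=per_unit / params.c_m,
        per_unit=per_unit,
        raw_per_unit=raw,
        bias_per_unit=bias,
        alpha_collapse=alpha_collapse,
        window=(window[0] * alpha_collapse, window[1] * alpha_collapse),
        n_points=n_window_points,
    )


def phase_diagram(
    gen_factory_for: Callable[[float, float], Callable[[int], PatternSet]],
    params: NetworkParams,
    zeta_grid: Sequence[float],
    f_grid: Sequence[float],
    n_cues: int = 12,
    seed: int = 0,
    **kwargs,
) -> np.ndarray:
    """Residual information per connection on a (zeta, f) grid.

    ``gen_factory_for(zeta, f)`` must return a pattern source callable at any
    p.  Cells where the measurement fails (no collapse within the cap) are
    recorded as NaN with a warning, not fatal.
    """
    out = np.full((len(f_grid), len(zeta_grid)), np.nan)
    for i, f in enumerate(f_grid):
        for j, zeta in enumerate(zeta_grid):
            try:
                ri = measure_residual_information(
                    gen_factory_for(zeta, f), params, n_cues=n_cues, seed=seed,
                    **kwargs,
                )
                out[i, j] = ri.per_connection
            except ValueError as err:  # pragma: no cover - defensive
                warnings.warn(
                    f"phase diagram cell (zeta={zeta}, f={f}) failed: {err}",
                    stacklevel=2,
                )
    return out


def cluster_patterns(patterns: PatternSet, n_clusters: int = 10, **kwargs):
    """Convenience hook: agglomerative clustering of the stored patterns on
    their Potts distances (complete linkage by default)."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    from .correlations import potts_distance

    D = potts_distance(patterns).D
    Z = linkage(squareform(D, checks=False), method=kwargs.pop("method", "complete"))
    return fcluster(Z, t=n_clusters, criterion="maxclust")
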