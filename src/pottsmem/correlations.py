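"""Correlation and distance statistics over Potts pattern sets.

Two complementary views are computed from an ``N x p`` pattern matrix:

* pattern-pattern correlations ``C_as``: the fraction of active units of one
  pattern that are co-active *and in the same state* in another, normalized
  by the nominal sparsity ``a``;
* unit-unit correlations ``C_ij``: the fraction of patterns in which two
  units are co-active in the same state.

A Potts distance between patterns combines active/quiescent mismatches and
same-active-different-state mismatches,

    D = C_a0 + C_0a + 2 * C_ad,

all three terms expressed as fractions of N, so D is scale-free in [0, 2].

The module also provides the shared-parent decomposition of the correlation
distribution, the block-averaged (hierarchical-approximation) matrices used
to construct soft and strict tree surrogates of a correlation matrix, and
the semantic-dominance profile (sorted summed feature weights with an
exponential fit, whose rate estimates the dominance parameter zeta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .patterns import PatternSet

__all__ = [
    "CorrelationSummary",
    "DistanceMatrix",
    "pattern_correlation",
    "unit_correlation",
    "correlation_summary",
    "potts_distance",
    "shared_parent_decomposition",
    "block_average",
    "correlation_to_distance",
    "dominance_profile",
]


def _state_indicators(xi: np.ndarray, S: int) -> list[np.ndarray]:
    return [(xi == k).astype(np.float64) for k in range(1, S + 1)]


def _same_state_counts(patterns: PatternSet) -> np.ndarray:
    """(p, p) matrix of counts of units co-active in the same state."""
    xi = patterns.xi
    out = np.zeros((patterns.p, patterns.p))
    for X in _state_indicators(xi, patterns.S):
        out += X.T @ X
    return out


def pattern_correlation(patterns: PatternSet) -> np.ndarray:
    """C_as[mu, nu] = (1 / (N a)) * #{i : xi_i^mu = xi_i^nu != 0}."""
    return _same_state_counts(patterns) / (patterns.N * patterns.a)


def unit_correlation(patterns: PatternSet) -> np.ndarray:
    """C[i, j] = (1 / (p a)) * #{mu : xi_i^mu = xi_j^mu != 0}."""
    xi = patterns.xi
    out = np.zeros((patterns.N, patterns.N))
    for X in _state_indicators(xi, patterns.S):
        out += X @ X.T
    return out / (patterns.p * patterns.a)


def _offdiag(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _moments(x: np.ndarray) -> dict[str, float]:
    mean = float(np.mean(x))
    sd = float(np.std(x))
    skew = float(np.mean(((x - mean) / sd) ** 3)) if sd > 0 else 0.0
    return {"mean": mean, "sd": sd, "skewness": skew}


@dataclass
class CorrelationSummary:
    """Pattern and unit correlation matrices with off-diagonal moments."""

    C_pattern: np.ndarray
    C_unit: np.ndarray
    pattern_moments: dict[str, float]
    unit_moments: dict[str, float]


def correlation_summary(patterns: PatternSet) -> CorrelationSummary:
    C_pattern = pattern_correlation(patterns)
    C_unit = unit_correlation(patterns)
    return CorrelationSummary(
        C_pattern=C_pattern,
        C_unit=C_unit,
        pattern_moments=_moments(_offdiag(C_pattern)),
        unit_moments=_moments(_offdiag(C_unit)),
    )


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pattern distances, as fractions of N."""

    D: np.ndarray
    convention: str = "fraction_of_N"

    @property
    def n_items(self) -> int:
        return self.D.shape[0]


def potts_distance(patterns: PatternSet) -> DistanceMatrix:
    """D = C_a0 + C_0a + 2 C_ad, each term a fraction of N.

    C_a0 (active in mu, quiescent in nu), C_0a (the reverse) and C_ad
    (co-active, different states) are computed from the co-activity and
    same-state counts; identical patterns are at distance 0.
    """
    xi = patterns.xi
    active = (xi != 0).astype(np.float64)
    n_active = active.sum(axis=0)  # realized per-pattern activity
    coactive = active.T @ active
    same = _same_state_counts(patterns)
    C_ad = (coactive - same) / patterns.N
    C_a0 = (n_active[:, None] - coactive) / patterns.N
    C_0a = (n_active[None, :] - coactive) / patterns.N
    D = C_a0 + C_0a + 2.0 * C_ad
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D=D)


def shared_parent_decomposition(
    C_pattern: np.ndarray, patterns: PatternSet
) -> dict[int, dict[str, float]]:
    """Group unordered pattern pairs by their number of shared parents.

    Returns ``{n_shared: {"count": ..., "mean": ..., "sd": ...}}``.  Requires
    the pattern set to carry its parent assignment (multi-parent generator).
    """
    if patterns.assignment is None:
        raise ValueError("pattern set carries no parent assignment")
    membership = patterns.assignment.membership.astype(np.int32)
    shared = membership.T @ membership  # (p, p)
    iu = np.triu_indices(patterns.p, k=1)
    shared_pairs = shared[iu]
    corr_pairs = C_pattern[iu]
    out: dict[int, dict[str, float]] = {}
    for n in np.unique(shared_pairs):
        sel = corr_pairs[shared_pairs == n]
        out[int(n)] = {
            "count": int(sel.size),
            "mean": float(sel.mean()),
            "sd": float(sel.std()),
        }
    return out


def block_average(
    C: np.ndarray, labels: np.ndarray, mode: str = "soft"
) -> np.ndarray:
    """Replace entries of a symmetric matrix by block means over a partition.

    ``soft``: within-block entries become the block's off-diagonal mean and
    each off-block entry the mean over its cluster pair — the soft
    hierarchical surrogate.  ``strict``: off-block entries are replaced by
    the single overall off-block mean, yielding a strictly ultrametric
    (two-level) structure.  The diagonal is left untouched.  Blocks with a
    single item have no off-diagonal within entries and are left unchanged.
    """
    if mode not in ("soft", "strict"):
        raise ValueError(f"mode must be 'soft' or 'strict', got {mode!r}")
    labels = np.asarray(labels)
    out = np.array(C, dtype=np.float64, copy=True)
    diag = np.diag(C).copy()
    uniq = np.unique(labels)
    masks = {lab: labels == lab for lab in uniq}
    offblock_vals = []
    for i_lab in uniq:
        for j_lab in uniq:
            mi, mj = masks[i_lab], masks[j_lab]
            blk = C[np.ix_(mi, mj)]
            if i_lab == j_lab:
                n = blk.shape[0]
                if n > 1:
                    mean = (blk.sum() - np.trace(blk)) / (n * (n - 1))
                    out[np.ix_(mi, mj)] = mean
            else:
                offblock_vals.append(blk.ravel())
                out[np.ix_(mi, mj)] = blk.mean()
    if mode == "strict" and offblock_vals:
        overall = float(np.concatenate(offblock_vals).mean())
        for i_lab in uniq:
            for j_lab in uniq:
                if i_lab != j_lab:
                    out[np.ix_(masks[i_lab], masks[j_lab])] = overall
    np.fill_diagonal(out, diag)
    return out


def correlation_to_distance(C: np.ndarray, kind: str = "one_minus") -> DistanceMatrix:
    """Turn a correlation/similarity matrix into quasi-distances.

    ``one_minus`` (d = 1 - C) is the labeled default; any user-supplied
    distance matrix can be used instead wherever a DistanceMatrix is accepted.
    """
    if kind != "one_minus":
        raise ValueError(f"unknown kind {kind!r}")
    D = 1.0 - np.asarray(C, dtype=float)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D=D, convention="one_minus_correlation")


def dominance_profile(
    weights: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Semantic-dominance profile of an items x features weight matrix.

    Sums the weights of each feature over items (s_j), sorts descending and
    fits ``log s_j ~ -zeta * rank`` by least squares; returns the sorted
    profile and the fitted rate.  Features with zero total weight cannot
    enter the log fit and are dropped with a warning.
    """
    weights = np.asarray(weights, dtype=np.float64)
    if weights.ndim != 2 or weights.shape[1] < 2:
        raise ValueError("weights must be an items x features matrix with >= 2 features")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    s = np.sort(weights.sum(axis=0))[::-1]
    positive = s > 0
    if not positive.all():
        warnings.warn(
            f"{int((~positive).sum())} feature(s) with zero total weight "
            "excluded from the exponential fit",
            stacklevel=2,
        )
    ranks = np.arange(1, s.size + 1)[positive]
    if ranks.size < 2:
        raise ValueError("need at least two positive feature sums to fit")
    slope, _ = np.polyfit(ranks, np.log(s[positive]), 1)
    return s, float(-slope)
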