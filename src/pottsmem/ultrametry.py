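"""Ultrametricity of a distance matrix via triplet edge-length ratios.

A metric space is ultrametric when every triangle is either equilateral or
isosceles with two long edges, i.e., for sorted edge lengths
``d_min <= d_med <= d_max`` of every triplet, ``d_med = d_max``.  The degree
to which a finite distance matrix approaches this limit is summarized here by
the *ultrametric content*, a scalar in [0, 1]:

1.  Off-diagonal distances are rank-uniformized (average ranks for ties,
    scaled to (0, 1]).  This makes the index invariant under any monotone
    transformation of the distances, so that different distance conventions
    derived from the same similarity structure give the same answer, and it
    fixes the reference scale: for exchangeable, structure-free distances the
    index has the closed-form baseline 7/18 ~ 0.389.
2.  For each (sampled or enumerated) triplet of items the sorted standardized
    edges give the ratio pair ``(x, y) = (d_min/d_max, d_med/d_max)``.
3.  The index is the mean over triplets of

        u = [(d_med - d_min) / (d_max - d_min)] * (d_med / d_max)
          = [(y - x) / (1 - x)] * y,

    with u = y for degenerate spreads (d_max = d_min, the equilateral case).

``u = 1`` exactly on every triangle of a strictly ultrametric space
(isosceles-with-two-long-edges have y = 1; equilateral triangles count fully),
so any strict two-level block hierarchy scores exactly 1.  Tight clusters
raise the index because triplets straddling a cluster boundary are isosceles
with two long edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .correlations import DistanceMatrix

__all__ = [
    "TripletRatios",
    "triplet_ratios",
    "ultrametric_content",
    "rank_standardize",
]

#: items up to which all C(n,3) triplets are enumerated rather than sampled
EXHAUSTIVE_LIMIT = 300
#: default number of sampled triplets above the exhaustive limit
DEFAULT_SAMPLE = 100_000

IID_BASELINE = 7.0 / 18.0  # exact triplet-index mean for i.i.d. distances


@dataclass
class TripletRatios:
    """Sorted edge-length ratio pairs of item triplets.

    ``ratios[:, 0] = d_min/d_max`` and ``ratios[:, 1] = d_med/d_max``;
    ``n_degenerate`` counts triplets excluded because ``d_max = 0``
    (duplicate items), for which the ratios are undefined.
    """

    ratios: np.ndarray  # (n_triplets, 2)
    n_triplets: int
    n_degenerate: int
    sampling: str  # "exhaustive" or "sample(M, seed)"
    standardize: str = "rank"


def rank_standardize(D: np.ndarray) -> np.ndarray:
    """Map off-diagonal distances to their average ranks scaled to (0, 1]."""
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    r = rankdata(D[iu]) / iu[0].size
    out = np.zeros_like(D, dtype=np.float64)
    out[iu] = r
    return out + out.T


def _as_matrix(dist: DistanceMatrix | np.ndarray) -> np.ndarray:
    D = dist.D if isinstance(dist, DistanceMatrix) else np.asarray(dist, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if D.shape[0] < 3:
        raise ValueError("need at least 3 items to form triplets")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distances must be nonnegative")
    return D


def _exhaustive_edges(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    chunks = []
    for i in range(n - 2):
        j, k = np.triu_indices(n - i - 1, k=1)
        j = j + i + 1
        k = k + i + 1
        chunks.append(np.stack([D[i, j], D[i, k], D[j, k]], axis=1))
    return np.concatenate(chunks, axis=0)


def _sampled_edges(D: np.ndarray, m: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n = D.shape[0]
    out = np.empty((0, 3))
    while out.shape[0] < m:
        idx = rng.integers(0, n, size=(int((m - out.shape[0]) * 1.4) + 16, 3))
        ok = (
            (idx[:, 0] != idx[:, 1])
            & (idx[:, 0] != idx[:, 2])
            & (idx[:, 1] != idx[:, 2])
        )
        idx = idx[ok]
        d = np.stack(
            [D[idx[:, 0], idx[:, 1]], D[idx[:, 0], idx[:, 2]], D[idx[:, 1], idx[:, 2]]],
            axis=1,
        )
        out = np.concatenate([out, d], axis=0)
    return out[:m]


def triplet_ratios(
    dist: DistanceMatrix | np.ndarray,
    sample: int | None = None,
    seed: int = 0,
    standardize: str = "rank",
) -> TripletRatios:
    """Extract (d_min/d_max, d_med/d_max) ratio pairs over item triplets.

    Triplets are enumerated exhaustively for up to ``EXHAUSTIVE_LIMIT`` items
    and uniformly sampled (``sample`` triplets, default 1e5) above; pass
    ``sample`` explicitly to force sampling.  ``standardize="rank"`` (default)
    rank-uniformizes distances first, ``"none"`` uses them as given.
    """
    D = _as_matrix(dist)
    if standardize == "rank":
        D = rank_standardize(D)
    elif standardize != "none":
        raise ValueError(f"unknown standardize mode {standardize!r}")
    n = D.shape[0]
    if sample is None and n <= EXHAUSTIVE_LIMIT:
        edges = _exhaustive_edges(D)
        sampling = "exhaustive"
    else:
        m = sample if sample is not None else DEFAULT_SAMPLE
        edges = _sampled_edges(D, m, seed)
        sampling = f"sample({m}, seed={seed})"
    edges.sort(axis=1)
    degenerate = edges[:, 2] <= 0
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        if n_degenerate == edges.shape[0]:
            warnings.warn("all triplets degenerate (zero distances)", stacklevel=2)
        edges = edges[~degenerate]
    ratios = edges[:, :2] / edges[:, 2:3]
    return TripletRatios(
        ratios=ratios,
        n_triplets=ratios.shape[0],
        n_degenerate=n_degenerate,
        sampling=sampling,
        standardize=standardize,
    )


def ultrametric_content(ratios: TripletRatios) -> float:
    """Mean of ``[(y - x)/(1 - x)] * y`` over the triplet ratio cloud.

    Equals 1 for strictly ultrametric inputs, ~7/18 for structureless
    (exchangeable) distances under rank standardization, and is invariant
    under item relabeling and global rescaling of the distances.
    """
    if ratios.n_triplets == 0:
        raise ValueError("empty triplet set: ultrametric content undefined")
    x = ratios.ratios[:, 0]
    y = ratios.ratios[:, 1]
    span = 1.0 - x
    u = np.where(span > 1e-12, (y - x) / np.where(span > 1e-12, span, 1.0), 1.0) * y
    return float(np.mean(u))
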