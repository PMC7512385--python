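"""Generative models of sparse Potts activity patterns.

Three generators are provided:

* :func:`generate_uncorrelated` — i.i.d. patterns where each unit is quiescent
  with probability ``1 - a`` and in any of the ``S`` active states with
  probability ``a/S``.
* :func:`generate_single_parent` — the classic single-parent (ultrametric)
  scheme for binary units, where each child is a noisy copy of one parent.
* :func:`generate` — the multi-parent ("feature") algorithm: non-sparse
  parent patterns push assigned children toward their own Potts states, with
  per-parent strengths damped exponentially by rank (the dominance rate
  ``zeta``), and the fraction ``a`` of units with the strongest total input
  is activated in each child.

The multi-parent algorithm is the package's central object: its three
parameters — extent ``a_p`` (probability a parent reaches a given unit),
prolificity ``f`` (fraction of children each parent influences) and dominance
``zeta`` (exponential imbalance between parents) — span pattern ensembles
ranging from effectively uncorrelated to ultrametric to non-trivially
clustered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "GenerationParams",
    "ParentPatterns",
    "ParentAssignment",
    "FieldTensor",
    "PatternSet",
    "generate_uncorrelated",
    "generate_parents",
    "assign_parents",
    "child_fields",
    "field_moments",
    "select_active",
    "generate",
    "generate_single_parent",
]


class ParameterError(ValueError):
    """Raised when generation or network parameters are out of range."""


@dataclass(frozen=True)
class GenerationParams:
    """Parameters of the multi-parent pattern generator.

    Parameters
    ----------
    N : int
        Number of Potts units.
    S : int
        Number of active states per unit (the quiescent state is extra).
    a : float
        Sparsity: fraction of active units per pattern, in (0, 1).
    n_parents : int
        Number of parents (features), Pi.
    n_children : int
        Number of child patterns, p.
    f : float
        Prolificity: fraction of all children each parent is assigned to,
        so that ``p_par = round(f * p)`` and the mean number of parents per
        child is ``Pi * f``.
    a_p : float
        Extent of parent input: probability that an assigned parent
        contributes input at any given unit of a child.
    zeta : float
        Dominance rate: parent pi (ranked 1..Pi) has its input damped by
        ``exp(-zeta * pi)``.  ``1/zeta`` is roughly the number of parents
        that effectively dominate.
    eps_max : float
        Scale of the strictly positive tie-breaking input added to every
        (child, unit, state) field.  Must be << a_p when a_p > 0.
    seed : int
        Seed for the generator's own RNG stream.
    """

    N: int
    S: int
    a: float
    n_parents: int = 150
    n_children: int = 1000
    f: float = 0.05
    a_p: float = 0.4
    zeta: float = 0.0
    eps_max: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.a < 1.0):
            raise ParameterError(f"sparsity a must lie in (0, 1), got {self.a}")
        if self.S < 1:
            raise ParameterError(f"S must be a positive integer, got {self.S}")
        if self.N < 1 or self.n_parents < 1 or self.n_children < 1:
            raise ParameterError("N, n_parents and n_children must be >= 1")
        if not (0.0 <= self.a_p <= 1.0):
            raise ParameterError(f"extent a_p must lie in [0, 1], got {self.a_p}")
        if not (0.0 < self.f <= 1.0):
            raise ParameterError(f"prolificity f must lie in (0, 1], got {self.f}")
        if self.zeta < 0.0:
            raise ParameterError(f"dominance zeta must be >= 0, got {self.zeta}")
        if self.n_active < 1:
            raise ParameterError("floor(a * N) must be at least 1")
        if self.eps_max <= 0.0:
            raise ParameterError("eps_max must be positive")

    @property
    def a_tilde(self) -> float:
        """Per-active-state probability a/S."""
        return self.a / self.S

    @property
    def n_active(self) -> int:
        """Number of active units per pattern, floor(a * N)."""
        return int(math.floor(self.a * self.N))

    @property
    def p_par(self) -> int:
        """Children per parent, round(f * p)."""
        return int(round(self.f * self.n_children))


@dataclass(frozen=True)
class ParentPatterns:
    """Non-sparse parent (feature) patterns: every unit in an active state."""

    states: np.ndarray  # (n_parents, N), entries in 1..S

    @property
    def n_parents(self) -> int:
        return self.states.shape[0]


@dataclass(frozen=True)
class ParentAssignment:
    """Which parents influence which children."""

    membership: np.ndarray  # (n_parents, n_children) bool

    @property
    def n_p(self) -> np.ndarray:
        """Number of parents per child (column sums)."""
        return self.membership.sum(axis=0)


@dataclass(frozen=True)
class FieldTensor:
    """Pre-threshold fields h[child, unit, state], all entries > 0."""

    h: np.ndarray  # (n_children, N, S)


@dataclass
class PatternSet:
    """N x p integer matrix of Potts states (0 = quiescent) plus metadata.

    ``meta`` records the generator name, its parameters, the seed and the
    sparsity mode: ``"exact"`` when every column has exactly floor(a*N)
    active units (rank-based selection), ``"bernoulli"`` when sparsity only
    holds in expectation.  Provenance objects (parents, assignment) are kept
    when the multi-parent generator produced the set, for downstream
    parent-overlap and shared-parent analyses.
    """

    xi: np.ndarray  # (N, p) int, entries in 0..S
    N: int
    S: int
    a: float
    meta: dict[str, Any] = field(default_factory=dict)
    parents: ParentPatterns | None = None
    assignment: ParentAssignment | None = None

    @property
    def p(self) -> int:
        return self.xi.shape[1]

    @property
    def a_tilde(self) -> float:
        return self.a / self.S

    def validate(self) -> None:
        if self.xi.shape[0] != self.N:
            raise ValueError("xi row count does not match N")
        if self.xi.min() < 0 or self.xi.max() > self.S:
            raise ValueError(f"pattern states must lie in 0..{self.S}")
        if self.meta.get("sparsity") == "exact":
            n_active = int(math.floor(self.a * self.N))
            counts = (self.xi != 0).sum(axis=0)
            if not np.all(counts == n_active):
                raise ValueError("exact-sparsity pattern set violates active count")


def generate_uncorrelated(params: GenerationParams) -> PatternSet:
    """I.i.d. patterns: quiescent w.p. 1-a, each active state w.p. a/S.

    Sparsity here is Bernoulli per unit (not exact-count); the metadata
    flags this.  The parent-related parameters of ``params`` are ignored.
    """
    rng = np.random.default_rng(params.seed)
    u = rng.random((params.N, params.n_children))
    xi = np.zeros((params.N, params.n_children), dtype=np.int32)
    active = u < params.a
    xi[active] = rng.integers(1, params.S + 1, size=int(active.sum()))
    return PatternSet(
        xi=xi,
        N=params.N,
        S=params.S,
        a=params.a,
        meta={
            "generator": "uncorrelated",
            "sparsity": "bernoulli",
            "seed": params.seed,
            "params": {"N": params.N, "S": params.S, "a": params.a},
        },
    )


def generate_parents(params: GenerationParams) -> ParentPatterns:
    """Draw Pi non-sparse parents, each unit uniform over the S active states."""
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    states = rng.integers(1, params.S + 1, size=(params.n_parents, params.N)).astype(
        np.int32
    )
    return ParentPatterns(states=states)


def assign_parents(params: GenerationParams) -> ParentAssignment:
    """Assign each parent to p_par = round(f*p) children, uniformly without
    replacement.

    The per-child parent count n_p is then Binomial(Pi, f) to excellent
    approximation (exactly hypergeometric mixing over parents).
    """
    if params.p_par < 1:
        raise ParameterError(
            f"round(f * p) = {params.p_par} < 1: each parent needs at least one child"
        )
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    membership = np.zeros((params.n_parents, params.n_children), dtype=bool)
    for pi in range(params.n_parents):
        children = rng.choice(params.n_children, size=params.p_par, replace=False)
        membership[pi, children] = True
    return ParentAssignment(membership=membership)


def field_moments(n_p: float, a_p: float) -> tuple[float, float]:
    """Mean and s.d. of the total field of a unit with n_p parents (S=1,
    zeta=0): ``(n_p a_p / 2, sqrt(n_p a_p (1/3 - a_p/4)))``."""
    if n_p < 0:
        raise ParameterError(f"n_p must be >= 0, got {n_p}")
    if not (0.0 <= a_p <= 1.0):
        raise ParameterError(f"a_p must lie in [0, 1], got {a_p}")
    mean = n_p * a_p / 2.0
    sd = math.sqrt(n_p * a_p * (1.0 / 3.0 - a_p / 4.0))
    return mean, sd


def child_fields(
    params: GenerationParams,
    parents: ParentPatterns,
    assignment: ParentAssignment,
) -> FieldTensor:
    """Accumulate parent inputs into per-(child, unit, state) fields.

    Each parent pi (ranked 1..Pi) assigned to child mu contributes, at every
    unit i independently with probability ``a_p``, a magnitude
    ``Uniform(0, 1] * exp(-zeta * pi)`` to the state ``parents.states[pi, i]``.
    A strictly positive tie-breaking term Uniform(0, eps_max] is added to
    every state's field, so that units without parent input align with a
    random state.

    Parent states are fixed per (parent, unit) across all children; the
    Bernoulli(a_p) gating and the magnitudes are redrawn per child.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 3]))
    p, N, S = params.n_children, params.N, params.S
    # tie-break noise on (0, eps_max]
    h = (1.0 - rng.random((p, N, S))) * params.eps_max
    cols = np.arange(N)
    for pi in range(params.n_parents):
        children = np.flatnonzero(assignment.membership[pi])
        if children.size == 0:
            continue
        damp = math.exp(-params.zeta * (pi + 1))
        gate = rng.random((children.size, N)) < params.a_p
        mag = (1.0 - rng.random((children.size, N))) * damp
        target = parents.states[pi] - 1  # (N,)
        # each (child, unit) pair is touched once per parent: plain fancy
        # indexing accumulates correctly
        h[children[:, None], cols[None, :], target[None, :]] += np.where(
            gate, mag, 0.0
        )
    if not np.all(np.isfinite(h)):
        raise FloatingPointError("non-finite fields")
    return FieldTensor(h=h)


def select_active(
    fields: FieldTensor, a: float, S: int
) -> tuple[np.ndarray, np.ndarray]:
    """Rank-based activation: per child, each unit's candidate state is the
    argmax over states of its field; the floor(a*N) units with the largest
    maximal fields become active in their candidate state, the rest are
    quiescent.

    Returns ``(xi, H_m)`` where ``xi`` is (N, p) and ``H_m[mu]`` is the
    empirical activation threshold of child mu (smallest retained field).
    """
    h = fields.h
    if not np.all(np.isfinite(h)):
        raise ValueError("non-finite fields")
    p, N, _ = h.shape
    n_active = int(math.floor(a * N))
    candidate = np.argmax(h, axis=2) + 1  # (p, N)
    H = np.max(h, axis=2)  # (p, N)
    xi = np.zeros((N, p), dtype=np.int32)
    if n_active >= N:
        xi[:] = candidate.T
        H_m = H.min(axis=1)
        return xi, H_m
    # indices of the n_active largest H per child
    part = np.argpartition(H, N - n_active, axis=1)[:, N - n_active:]
    rows = np.arange(p)[:, None]
    xi[part, rows] = candidate[rows, part]
    H_m = H[rows, part].min(axis=1)
    return xi, H_m


def generate(params: GenerationParams) -> PatternSet:
    """Run the full multi-parent algorithm: parents -> assignment -> fields
    -> rank-based activation.  The returned set stores the parents and the
    assignment for downstream analyses (parent overlaps, shared-parent
    correlation decomposition)."""
    parents = generate_parents(params)
    assignment = assign_parents(params)
    fields = child_fields(params, parents, assignment)
    xi, H_m = select_active(fields, params.a, params.S)
    return PatternSet(
        xi=xi,
        N=params.N,
        S=params.S,
        a=params.a,
        meta={
            "generator": "multi_parent",
            "sparsity": "exact",
            "seed": params.seed,
            "params": {
                "N": params.N,
                "S": params.S,
                "a": params.a,
                "n_parents": params.n_parents,
                "n_children": params.n_children,
                "f": params.f,
                "a_p": params.a_p,
                "zeta": params.zeta,
                "eps_max": params.eps_max,
            },
            "H_m": H_m,
        },
        parents=parents,
        assignment=assignment,
    )


def generate_single_parent(
    N: int,
    n_parents: int,
    children_per_parent: int,
    a: float,
    b: float,
    seed: int = 0,
) -> PatternSet:
    """Single-parent (ultrametric) generator for binary units.

    Parents are i.i.d. Bernoulli(a); each child of parent pi is active at
    unit i with probability ``a + b * (xi_parent - a)``: b=0 gives
    independent children, b=1 exact copies of the parent.  Sparsity is
    Bernoulli, flagged in the metadata.
    """
    if not (0.0 <= b <= 1.0):
        raise ParameterError(f"branching parameter b must lie in [0, 1], got {b}")
    if not (0.0 < a < 1.0):
        raise ParameterError(f"sparsity a must lie in (0, 1), got {a}")
    rng = np.random.default_rng(seed)
    parents = (rng.random((n_parents, N)) < a).astype(np.int32)
    p = n_parents * children_per_parent
    parent_of = np.repeat(np.arange(n_parents), children_per_parent)
    prob = a + b * (parents[parent_of] - a)  # (p, N)
    xi = (rng.random((p, N)) < prob).astype(np.int32).T  # (N, p)
    return PatternSet(
        xi=xi,
        N=N,
        S=1,
        a=a,
        meta={
            "generator": "single_parent",
            "sparsity": "bernoulli",
            "seed": seed,
            "params": {
                "N": N,
                "n_parents": n_parents,
                "children_per_parent": children_per_parent,
                "a": a,
                "b": b,
            },
            "parent_of": parent_of,
        },
        parents=ParentPatterns(states=parents),
    )
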