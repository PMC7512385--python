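# Methods

This note records the models implemented in `pottsmem`, the choices made
where the underlying procedures are open to interpretation, and what the
package's synthetic benchmarks do and do not establish.

## The Potts associative network

Each of `N` Potts units abstracts a local cortical patch; it can be quiescent
(state 0) or in one of `S` active states (local attractors). A network
*pattern* assigns one state per unit; stored patterns are sparse: a fraction
`a` of units is active, each active state equally likely (per-state
probability ã = a/S).

Patterns are stored with the covariance Hebbian rule on a randomly diluted
directed graph (each edge present independently with probability `c_m/N`):

    J_ij^kl = 1/(c_m a (1 − ã)) Σ_μ (δ(ξ_i^μ,k) − ã)(δ(ξ_j^μ,l) − ã),

for active k, l only. Retrieval dynamics are sequential Glauber-style sweeps
at inverse temperature β with a firing threshold U:

    σ_ik = exp(β h_ik) / (exp(β U) + Σ_l exp(β h_il)).

**Threshold convention.** The source equations carry U both as a `−U` term in
the active-state fields and as the `exp(βU)` weight of the quiescent state;
applying both double-counts it. We keep the quiescent pseudo-state weight
`exp(βU)` and no `−U` in the active fields — equivalent to any other
placement up to a common shift of all fields, which the update rule ignores
(max-subtraction also makes it numerically safe at β = 200, the default).

**Update schedule.** One sweep updates all units sequentially in a fresh
random permutation. Convergence is declared when the largest per-unit
activity change in a sweep falls below 1e-6 (default cap 100 sweeps);
non-convergence is reported, not raised. All randomness flows through
explicitly seeded `numpy` generators.

**Defaults** mirror the reference setting of the storage-capacity analyses:
`N=2000, c_m=200, S=5, a=0.1, U=0.5, β=200` at full scale; the reduced
network used by the heavier scans is `N=1000, c_m=100` at the same dilution
`c_m/N = 0.1`.

## Generating correlated patterns (the multi-parent model)

Concepts (child patterns) are generated from features (parents):

1. Π parents are drawn non-sparse: every unit uniform over the S active
   states.
2. Each parent is assigned `p_par = round(f·p)` children uniformly without
   replacement (prolificity `f`); a child's parent count is Binomial(Π, f).
3. Each assigned parent π (globally ranked 1..Π) contributes, at every unit
   independently with probability `a_p` (extent), a magnitude
   `Uniform(0,1] · exp(−ζ·π)` to the field of the parent's state at that
   unit (dominance rate ζ). A tie-break input `Uniform(0, ε_max]`,
   `ε_max = 1e-6`, is added to every (child, unit, state).
4. Per child, each unit's candidate state is the field argmax; the
   `floor(a·N)` units with the largest fields become active (rank-based
   activation, exact sparsity).

Interpretive choices, in decreasing order of consequence:

- **Parent states are fixed per (parent, unit) across children** — required
  for parents to be patterns with which factor overlaps can be computed —
  while the gating and magnitudes are redrawn per child (the input notation
  carries both the parent and the child index; per-child redraw is the
  weaker correlation assumption and matches the measured field moments).
- **Rank-based activation** (top `floor(a·N)` units) instead of the
  distributional threshold: it realizes exact per-pattern sparsity, makes
  self-overlaps exactly 1, and matches the verbal three-stage description;
  the analytic threshold remains available as the per-child `H_m` output.
- **Tie-break scale.** ε only needs to order states on units without parent
  input. It does, however, set where exponentially damped parents drown:
  parent rank π stops influencing children once `exp(−ζπ) ≲ ε`. With
  `ε_max = 1e-6` the dominance-driven cluster structure survives to
  ζ ~ ln(1/ε)/2 ≈ 7. This matters for the upper boundary of the residual
  information phase (below).
- The field-moment formulas for a unit with n_p parents (S=1, ζ=0) are
  mean `n_p a_p/2` and s.d. `sqrt(n_p a_p (1/3 − a_p/4))`; the generator is
  validated against them at 3 standard errors.

The single-parent (ultrametric) generator and the i.i.d. generator are kept
as reference limits, with Bernoulli (not exact-count) sparsity flagged in
their metadata.

## Correlation and distance statistics

`C_as(μ,ν)` is the fraction of units co-active in the same state, normalized
by the nominal `a` (exact for rank-based patterns). The Potts distance is
`D = C_a0 + C_0a + 2 C_ad` with all three terms as fractions of N, so
`D ∈ [0, 2]` independent of N; for exact-count patterns it reduces to an
affine function of `C_as`. The semantic-dominance profile sums feature
weights over items, sorts them, and fits `log s_j ~ −ζ·rank` by least
squares; zero-sum features are excluded from the fit with a warning.

## Ultrametric content

The index quantifies how close the triplet geometry of a distance matrix is
to a tree (every triangle equilateral or isosceles with two long edges). The
definition used here:

1. rank-uniformize the off-diagonal distances (average ranks for ties,
   scaled to (0,1]);
2. for each triplet with sorted edges d_min ≤ d_med ≤ d_max, compute
   `u = [(d_med − d_min)/(d_max − d_min)] · (d_med/d_max)` (u = y for
   degenerate spread);
3. average u over all triplets (exhaustive up to 300 items, otherwise 1e5
   sampled triplets, seeded). Triplets with d_max = 0 are excluded and
   counted.

Properties that motivated this form: it is exactly 1 on any strict two-level
hierarchy; it is invariant under item relabeling and under *any monotone
transformation* of the distances — so correlation-derived quasi-distances
and the Potts distance give the same answer; and its expectation for
exchangeable (structure-free) distances is exactly 7/18 ≈ 0.389, which is
where the weakly-correlated ensembles land. Limitations: because ranks
discard the within-cluster distance scale, the index responds to clustering
through boundary-straddling triplets only; very tight clusters raise it less
than an index that also sees raw within-cluster coherence. The strongly
clustered ensembles (f = 0.2 with ζ ≥ 0.1) plateau near 0.42–0.43 under this
definition.

## Mean-field (SCSNA) capacity

The solver iterates (m, q, Ω) with damping, evaluating the zero-temperature
Gaussian and pattern averages by seeded Monte-Carlo (default 2e5 joint
draws, held fixed across iterations — common random numbers — so the
fixed-point search is smooth). The per-state noise amplitudes include the
correlation correction `1 + (p C̄/(a(1−ã)))(C̄ − ã)`, which is 1 for
uncorrelated patterns; `C̄` is measured from a generated pattern set, not
modeled. Two conventions required a decision:

- **Quiescent-state field.** Read literally, the mean-field expression gives
  the quiescent state its own noise channel with weight `P_0 = 1 − a`.
  Physically the quiescent state receives no couplings (the Hebbian rule
  carries `(1 − δ_k0)` factors) and its field is identically zero; we set
  `H_0 = 0`. With the literal reading the capacity comes out several-fold
  below simulation; with `H_0 = 0` the mean-field capacity agrees with
  simulation within ~10% for uncorrelated patterns at a ∈ {0.2, 0.3},
  c_m/N = 0.1, and over-estimates it at a = 0.1 and for correlated patterns
  — the behavior expected of this mean-field treatment, which neglects the
  fluctuations of the correlations beyond their mean.
- **Bracket placement** in the noise variance: implemented as the product of
  the dilution factor `1 + 2dΨ + dΨ²` and the correlation correction.

A solution exists when the damped iteration converges to m above 0.3;
capacity is found by bisection on α to 1e-2. Ties in the argmax (measure
zero) fall to the lower state index.

## Mutual information and the residual-information phase

The per-unit mutual information between the cued pattern and the graded
final state uses the plug-in estimator on the joint state-occupancy matrix
(0·log 0 = 0); the final σ is used directly, not its argmax discretization.
The plug-in estimator is biased upward by about `(S+1)²/(2N ln 2)` bits
(≈0.018 at N=1000), which would swamp a genuinely zero residual phase at
reduced scale, so every information run also evaluates a shuffle control
(the same final state paired with a unit-permuted cue) and residual
information is reported bias-corrected: info − shuffle. Raw and bias values
are retained.

**Residual information** is the mean bias-corrected information per
connection over loadings α ∈ [1.5, 2.5] × α_collapse, where α_collapse is
the loading at which the mean cue overlap first drops below 0.35 (half the
0.7 retrieval criterion). The collapse is located adaptively: geometric
growth of p with a small cue sample brackets it, bisection refines it to
~12%, then the window is evaluated at 3 loadings with the full cue count.

At the full reference scale (N=2000, c_m=200, f=0.05, a_p=0.4, ζ=0.1) this
yields ≈0.6e-3 bits/connection, about five times below the pattern entropy
per unit (0.701 bits), and ≈0 at ζ ≤ 0.003 — the phase of partial,
feature-level memory past the capacity collapse. On the half-decade ζ grid
the phase opens between 0.01 and 0.0316. Its closure is controlled by the
tie-break scale ε discussed above: with ε_max = 1e-6, clusters seeded by
parents of rank up to ~ln(1/ε)/ζ persist, and the measured residual
information remains ≥29% of its plateau through ζ = 10; the phase therefore
closes around ζ ~ 10–30 here rather than near 0.5. We regard the closure
point as ε-dependent rather than universal and keep ε at its small default,
which preserves the field-moment identities and the high-ζ structure of the
pattern ensembles.

## Problem sizes

Pattern-statistics analyses run at the full reference scale (N=2000,
p=1000). Network scans use N=1000, c_m=100 (same dilution) except the
headline residual-information measurement, which runs at N=2000, c_m=200
with 20 cues and 3 window loadings; capacity rank comparisons use 16–24
cues and a bisection resolution of 4–10%. These sizes were chosen so the
full suite completes in well under half an hour on one CPU while keeping
each assertion's noise margin at least ~3 standard errors.

## What the synthetic benchmarks do not show

All tests run on patterns from the package's own generators. They establish
the internal consistency of the generative model, the network, and the
analyses — not that real semantic-feature data have these statistics. The
dominance-profile and block-averaging operators accept external item-by-
feature weight matrices, but no claims about any particular corpus are
tested here. Finite-size effects at N ≤ 1000 (overlap noise ~(Na)^{-1/2},
MI estimator bias) are handled by normalization and bias subtraction but
not eliminated.
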