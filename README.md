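# pottsmem

Correlated semantic memory patterns and their storage in a Potts attractor
network.

Semantic memories are not independent of each other: concepts share features,
and the neural activity patterns that represent them are correlated in a way
that is neither trivial (all patterns equidistant) nor a simple tree
(concepts nested in categories). `pottsmem` implements, for computational
neuroscientists studying cortical memory models:

- a **generative model of correlated sparse Potts patterns**: child patterns
  ("concepts") are built from Π non-sparse parent patterns ("features"),
  with three parameters — the *extent* `a_p` (probability a parent reaches a
  given unit), the *prolificity* `f` (fraction of children each parent
  influences, so a child has Binomial(Π, f) parents), and the *dominance*
  `ζ` (parent strengths damped as `exp(−ζ·rank)`). Each unit of a child
  aligns with the state receiving the largest summed parental input, and the
  fraction `a` of units with the strongest inputs becomes active;
- the **diluted Potts autoassociative network** that stores such patterns
  with the covariance Hebbian rule
  `J_ij^kl ∝ Σ_μ (δ(ξ_i^μ,k) − a/S)(δ(ξ_j^μ,l) − a/S)` on a random directed
  graph with mean degree `c_m`, retrieving them with sequential
  Boltzmann-style dynamics at inverse temperature β against a threshold U;
- the **self-consistent signal-to-noise (mean-field) analysis** of its
  storage capacity `α_c = p/c_m`, including the correlation correction
  `1 + (p·C̄/(a(1−ã)))(C̄ − ã)` to the crosstalk noise;
- **analysis operators**: pattern/unit correlations, a Potts distance,
  shared-parent decompositions, block-averaged (soft/strict hierarchical)
  matrix surrogates, the semantic-dominance profile with its exponential-fit
  rate, a triplet-based **ultrametric content** index, and the **mutual
  information** between a cued pattern and the retrieved state — whose
  post-capacity-collapse plateau (the *residual information*) marks a phase
  in (ζ, f) where the network keeps gross, feature-level information about
  a cue even when the detailed memory is lost.

## Worked example

```python
import numpy as np
from pottsmem.patterns import GenerationParams, generate
from pottsmem.correlations import pattern_correlation, potts_distance
from pottsmem.ultrametry import triplet_ratios, ultrametric_content
from pottsmem.network import NetworkParams
from pottsmem.info import measure_residual_information, pattern_entropy

# 400 concepts from 150 features, moderate dominance
params = GenerationParams(N=1000, S=5, a=0.3, n_parents=150, n_children=400,
                          f=0.05, a_p=0.4, zeta=0.1, seed=1)
ps = generate(params)
C = pattern_correlation(ps)
off = C[np.triu_indices(ps.p, 1)]
print(f"mean pattern correlation {off.mean():.4f}  (a/S = {0.3/5})")
uc = ultrametric_content(triplet_ratios(potts_distance(ps), seed=1))
print(f"ultrametric content      {uc:.3f}")

# store and overload a network: what survives past the capacity collapse?
net = NetworkParams(N=1000, S=5, a=0.1, c_m=100, U=0.5, beta=200.0)
src = lambda p: generate(GenerationParams(N=1000, S=5, a=0.1, n_parents=150,
                                          n_children=p, f=0.05, a_p=0.4,
                                          zeta=0.1, seed=42))
ri = measure_residual_information(src, net, n_cues=12, n_cues_search=6, seed=3)
print(f"collapse loading         {ri.alpha_collapse:.2f}")
print(f"residual information     {ri.per_connection:.2e} bits/connection")
print(f"pattern entropy          {pattern_entropy(0.1, 5):.3f} bits/unit")
```

prints

```
mean pattern correlation 0.0656  (a/S = 0.06)
ultrametric content      0.396
collapse loading         4.37
residual information     7.06e-04 bits/connection
pattern entropy          0.701 bits/unit
```

Read: the generated concepts are correlated slightly above the independent
baseline a/S with a dominance-driven tail; after the network's retrieval
collapses (here at loading α ≈ 4.4), cueing a memory still recovers
≈ 0.7·10⁻³ bits per connection — information about the cue's dominant
feature, roughly five times below the full pattern entropy per unit. At
ζ ≤ 0.003 the same measurement returns ≈ 0.

A CLI mirrors the library (`pottsmem generate | analyze-correlations |
ultrametry | simulate | capacity | scsna | phase-diagram | fixtures`); every
subcommand writes a manifest with its resolved parameters and seeds.

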