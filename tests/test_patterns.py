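"""Unit tests for the pattern generators: i.i.d. statistics, parent
assignment, field accumulation and moments, rank-based activation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pottsmem.patterns import (
    GenerationParams,
    ParameterError,
    assign_parents,
    child_fields,
    field_moments,
    generate,
    generate_parents,
    generate_single_parent,
    generate_uncorrelated,
    select_active,
)
from pottsmem.correlations import pattern_correlation


def offdiag(m):
    return m[np.triu_indices(m.shape[0], 1)]


class TestUncorrelated:
    def test_mean_same_state_correlation_is_a_over_S(self):
        # i.i.d. patterns: mean pairwise same-state correlation a/S = 0.06
        ps = generate_uncorrelated(
            GenerationParams(N=2000, S=5, a=0.3, n_children=400, seed=1)
        )
        mean = offdiag(pattern_correlation(ps)).mean()
        assert mean == pytest.approx(0.06, abs=0.002)

    def test_degenerate_dense_binary_limit(self):
        ps = generate_uncorrelated(
            GenerationParams(N=50, S=1, a=0.999, n_children=10, seed=0)
        )
        assert (ps.xi == 1).mean() > 0.99

    def test_coactivity_counts_follow_binomial(self):
        # N a C_as ~ Binomial(N, a^2/S) for i.i.d. patterns; disjoint pattern
        # pairs keep the co-activity counts independent for the test
        N, a, S = 200, 0.2, 2
        ps = generate_uncorrelated(
            GenerationParams(N=N, S=S, a=a, n_children=2000, seed=7)
        )
        left, right = ps.xi[:, ::2], ps.xi[:, 1::2]
        counts = ((left == right) & (left != 0)).sum(axis=0)
        pr = a * a / S
        kmax = int(stats.binom.ppf(0.9999, N, pr))
        observed = np.bincount(np.clip(counts, 0, kmax + 1), minlength=kmax + 2)
        expected = stats.binom.pmf(np.arange(kmax + 1), N, pr)
        expected = np.append(expected, 1.0 - expected.sum()) * counts.size
        keep = expected >= 5
        chi2 = (((observed[keep] - expected[keep]) ** 2) / expected[keep]).sum()
        pval = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pval > 1e-3

    def test_invalid_sparsity_rejected(self):
        with pytest.raises(ParameterError):
            GenerationParams(N=100, S=2, a=1.2, n_children=5)
        with pytest.raises(ParameterError):
            GenerationParams(N=100, S=0, a=0.2, n_children=5)


class TestParents:
    def test_single_state_limit(self):
        pp = generate_parents(GenerationParams(N=30, S=1, a=0.5, n_parents=4,
                                               n_children=10, seed=0))
        assert (pp.states == 1).all()

    def test_states_uniform(self):
        params = GenerationParams(N=2000, S=5, a=0.3, n_parents=150,
                                  n_children=10, seed=3)
        pp = generate_parents(params)
        counts = np.bincount(pp.states.ravel(), minlength=6)[1:]
        chi = stats.chisquare(counts)
        assert chi.pvalue > 1e-3
        assert counts.sum() == 150 * 2000

    def test_seeded_determinism(self):
        params = GenerationParams(N=100, S=3, a=0.2, n_parents=10,
                                  n_children=20, seed=11)
        assert np.array_equal(generate_parents(params).states,
                              generate_parents(params).states)


class TestAssignment:
    def test_mean_parent_count_matches_binomial(self):
        # Pi f = 1.5 parents per child on average at f = 0.01
        params = GenerationParams(N=10, S=1, a=0.5, n_parents=150,
                                  n_children=1000, f=0.01, seed=5)
        n_p = assign_parents(params).n_p
        se = math.sqrt(150 * 0.01 * 0.99 / 1000)
        assert abs(n_p.mean() - 1.5) < 3 * se

    def test_full_prolificity(self):
        params = GenerationParams(N=10, S=1, a=0.5, n_parents=12,
                                  n_children=30, f=1.0, seed=5)
        assert (assign_parents(params).n_p == 12).all()

    def test_parent_count_distribution(self):
        params = GenerationParams(N=10, S=1, a=0.5, n_parents=150,
                                  n_children=4000, f=0.05, seed=6)
        n_p = assign_parents(params).n_p
        kmax = int(stats.binom.ppf(0.9999, 150, 0.05))
        observed = np.bincount(np.clip(n_p, 0, kmax + 1), minlength=kmax + 2)
        expected = stats.binom.pmf(np.arange(kmax + 1), 150, 0.05)
        expected = np.append(expected, 1 - expected.sum()) * 4000
        keep = expected >= 5
        chi2 = (((observed[keep] - expected[keep]) ** 2) / expected[keep]).sum()
        assert stats.chi2.sf(chi2, keep.sum() - 1) > 1e-3

    def test_too_few_children_per_parent_rejected(self):
        params = GenerationParams(N=10, S=1, a=0.5, n_parents=5,
                                  n_children=10, f=0.01, seed=5)
        with pytest.raises(ParameterError):
            assign_parents(params)


class TestFields:
    def test_moment_formulas(self):
        assert field_moments(0, 0.3) == (0.0, 0.0)
        mean, sd = field_moments(15, 0.4)
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(math.sqrt(15 * 0.4 * (1 / 3 - 0.1)))
        with pytest.raises(ParameterError):
            field_moments(-1, 0.4)

    @pytest.mark.parametrize("n_p", [15, 30, 50])
    def test_sample_moments_match_formulas(self, n_p):
        # S=1, zeta=0, every child has exactly n_p parents (f=1)
        params = GenerationParams(N=400, S=1, a=0.5, n_parents=n_p,
                                  n_children=60, f=1.0, a_p=0.4, seed=n_p)
        ft = child_fields(params, generate_parents(params),
                          assign_parents(params))
        h = ft.h.ravel()
        mean, sd = field_moments(n_p, 0.4)
        n = h.size
        assert abs(h.mean() - mean) < 3 * sd / math.sqrt(n) + params.eps_max
        # s.e. of the sample s.d. ~ sd / sqrt(2 n)
        assert abs(h.std() - sd) < 3 * sd / math.sqrt(2 * n) + params.eps_max

    def test_zero_extent_leaves_only_tiebreak(self):
        params = GenerationParams(N=50, S=3, a=0.2, n_parents=10,
                                  n_children=20, f=0.5, a_p=0.0, seed=1)
        ft = child_fields(params, generate_parents(params),
                          assign_parents(params))
        assert ft.h.max() <= params.eps_max
        assert ft.h.min() > 0


class TestSelectActive:
    def test_exact_count_and_candidate_states(self, tiny_multiparent):
        n_active = math.floor(0.25 * 100)
        assert ((tiny_multiparent.xi != 0).sum(axis=0) == n_active).all()
        tiny_multiparent.validate()

    def test_all_units_active_when_a_covers_n(self):
        params = GenerationParams(N=20, S=2, a=0.999, n_parents=4,
                                  n_children=6, f=0.5, seed=2)
        ft = child_fields(params, generate_parents(params),
                          assign_parents(params))
        xi, _ = select_active(ft, 0.999, 2)
        # a*N = 19.98 -> floor 19 active of 20
        assert ((xi != 0).sum(axis=0) == 19).all()

    def test_threshold_is_smallest_retained_field(self):
        params = GenerationParams(N=60, S=2, a=0.3, n_parents=8,
                                  n_children=10, f=0.5, seed=3)
        ft = child_fields(params, generate_parents(params),
                          assign_parents(params))
        xi, H_m = select_active(ft, 0.3, 2)
        H = ft.h.max(axis=2)
        for mu in range(10):
            active = xi[:, mu] > 0
            assert H[mu, active].min() == pytest.approx(H_m[mu])
            # quantile condition: all retained fields exceed all dropped ones
            assert H[mu, active].min() >= H[mu, ~active].max()


class TestGenerate:
    def test_active_state_marginal_uniform(self):
        ps = generate(GenerationParams(N=1000, S=5, a=0.3, n_parents=150,
                                       n_children=300, f=0.05, a_p=0.4, seed=4))
        counts = np.bincount(ps.xi.ravel(), minlength=6)
        frac = counts[1:] / counts[1:].sum()
        assert np.allclose(frac, 0.2, atol=0.01)

    def test_binary_units_give_uncorrelated_patterns(self):
        # for S=1 the algorithm's output is statistically uncorrelated
        base = dict(N=1500, S=1, a=0.2, n_parents=150, n_children=250,
                    f=0.05, a_p=0.4)
        mp = generate(GenerationParams(**base, seed=5))
        null = generate_uncorrelated(GenerationParams(**base, seed=6))
        c_mp = offdiag(pattern_correlation(mp))
        c0 = offdiag(pattern_correlation(null))
        assert abs(c_mp.mean() - c0.mean()) < 0.01
        assert c_mp.std() < 1.5 * c0.std()

    def test_vanishing_extent_recovers_random_statistics(self):
        ps = generate(GenerationParams(N=1500, S=5, a=0.3, n_parents=150,
                                       n_children=250, f=0.05, a_p=0.01, seed=7))
        mean = offdiag(pattern_correlation(ps)).mean()
        assert mean == pytest.approx(0.06, abs=0.003)

    def test_single_parent_regime_is_multimodal(self):
        # Pi f ~ 1: same-parent siblings form a separated high-correlation mode
        ps = generate(GenerationParams(N=1500, S=5, a=0.3, n_parents=150,
                                       n_children=600, f=0.01, a_p=1.0, seed=8))
        c = offdiag(pattern_correlation(ps))
        share = (ps.assignment.membership.astype(int).T
                 @ ps.assignment.membership.astype(int))
        shared = offdiag(share) > 0
        assert c[shared].mean() > c[~shared].mean() + 5 * c[~shared].std()

    def test_provenance_carried(self, tiny_multiparent):
        assert tiny_multiparent.parents is not None
        assert tiny_multiparent.assignment is not None
        assert tiny_multiparent.meta["generator"] == "multi_parent"


class TestSingleParentGenerator:
    def test_full_bias_copies_parent(self):
        ps = generate_single_parent(200, 5, 3, a=0.3, b=1.0, seed=1)
        parent_of = ps.meta["parent_of"]
        for mu in range(ps.p):
            assert np.array_equal(ps.xi[:, mu], ps.parents.states[parent_of[mu]])

    def test_zero_bias_independent_of_parent(self):
        ps = generate_single_parent(3000, 4, 2, a=0.3, b=0.0, seed=2)
        parent_of = ps.meta["parent_of"]
        cov = np.mean(
            (ps.xi.T - 0.3) * (ps.parents.states[parent_of] - 0.3)
        )
        assert abs(cov) < 0.005

    def test_sibling_covariance_gap(self):
        # same-parent minus different-parent child covariance = a(1-a) b^2
        a, b = 0.3, 0.5
        ps = generate_single_parent(4000, 40, 2, a=a, b=b, seed=3)
        xi = ps.xi.astype(float)
        same, diff = [], []
        for pi in range(40):
            c1, c2 = 2 * pi, 2 * pi + 1
            same.append(np.mean((xi[:, c1] - a) * (xi[:, c2] - a)))
            c3 = (2 * pi + 2) % ps.p
            diff.append(np.mean((xi[:, c1] - a) * (xi[:, c3] - a)))
        gap = np.mean(same) - np.mean(diff)
        assert gap == pytest.approx(a * (1 - a) * b * b, abs=0.006)

    def test_invalid_bias_rejected(self):
        with pytest.raises(ParameterError):
            generate_single_parent(10, 2, 2, a=0.3, b=1.5)


@settings(max_examples=20, deadline=None)
@given(
    N=st.integers(30, 120),
    S=st.integers(1, 4),
    a=st.floats(0.1, 0.6),
    zeta=st.floats(0.0, 2.0),
    seed=st.integers(0, 10_000),
)
def test_generated_patterns_satisfy_invariants(N, S, a, zeta, seed):
    """Exact sparsity and state range hold for any admissible parameters."""
    params = GenerationParams(N=N, S=S, a=a, n_parents=10, n_children=15,
                              f=0.3, a_p=0.5, zeta=zeta, seed=seed)
    ps = generate(params)
    assert ((ps.xi != 0).sum(axis=0) == math.floor(a * N)).all()
    assert ps.xi.min() >= 0 and ps.xi.max() <= S
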