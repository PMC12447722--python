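"""Stability, similarity, entropy and transition-bias metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from boolstab import (
    Attractor,
    attractor_similarity_approx,
    attractor_similarity_exact,
    build_report,
    build_transition_matrix,
    entropy_difference,
    enumerate_landscape,
    global_randomization_matrix,
    landscape_similarity,
    normalized_entropy,
    random_regular_network,
    stationary_distribution,
    trace_stability,
    transition_bias,
)
from boolstab.transition import TransitionMatrix

from conftest import constant_zero_net


def random_state_attractor(length: int, n_nodes: int, seed: int) -> Attractor:
    """Synthetic cycle whose states have i.i.d. uniform random bits.

    Not a dynamical attractor of any particular network; used to probe
    the similarity measures' random-state floor of 1/2.
    """
    rng = np.random.default_rng(seed)
    states = rng.integers(0, 1 << n_nodes, size=length, dtype=np.int64)
    return Attractor(tuple(int(s) for s in states))


class TestTraceStability:
    def test_swap_net_trace_zero(self, swap_net):
        L = enumerate_landscape(swap_net)
        assert trace_stability(build_transition_matrix(swap_net, L)) == 0.0

    def test_single_attractor(self):
        assert trace_stability(np.array([[1.0]])) == 1.0

    def test_baseline_trace_one(self):
        net = random_regular_network(10, 3, 0.3, seed=4)
        L = enumerate_landscape(net)
        assert trace_stability(global_randomization_matrix(L)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_added_diagonal_mass_never_decreases_trace(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = rng.integers(2, 6)
            m = rng.random((n, n))
            m /= m.sum(axis=1, keepdims=True)
            boosted = m + np.diag(rng.random(n))
            boosted /= boosted.sum(axis=1, keepdims=True)
            assert trace_stability(boosted) >= trace_stability(m) - 1e-12


class TestStationaryDistribution:
    def test_swap_net_hand_solution(self, swap_net):
        # the chain is periodic; time-average occupancy is (1/4, 1/2, 1/4)
        L = enumerate_landscape(swap_net)
        v = stationary_distribution(build_transition_matrix(swap_net, L))
        assert np.allclose(v, [0.25, 0.5, 0.25], atol=1e-12)

    def test_trivial_chain(self):
        assert stationary_distribution(np.array([[1.0]])).tolist() == [1.0]

    def test_baseline_recovers_basin_sizes(self):
        for seed in range(10):
            net = random_regular_network(10, 2, 0.4, seed)
            L = enumerate_landscape(net)
            v = stationary_distribution(global_randomization_matrix(L))
            assert np.allclose(v, L.basin_sizes, atol=1e-10)

    def test_left_eigenvector_residual(self):
        for seed in range(10):
            net = random_regular_network(11, 3, 0.35, seed)
            L = enumerate_landscape(net)
            M = build_transition_matrix(net, L)
            v = stationary_distribution(M)
            assert v.min() >= 0
            assert v.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.max(np.abs(v @ M.m - v)) <= 1e-10

    def test_reducible_chain_uniform_start_average(self):
        # two absorbing attractors reached symmetrically: equal weight
        m = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.5, 0.5, 0.0]])
        v, info = stationary_distribution(m, return_info=True)
        assert info["reducible"]
        assert np.allclose(v, [0.5, 0.5, 0.0], atol=1e-12)

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError):
            stationary_distribution(np.array([[0.5, 0.4], [0.5, 0.5]]))

    def test_agrees_with_dense_eigensolver_on_irreducible(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(2, 8))
            m = rng.random((n, n)) + 0.01  # strictly positive => irreducible
            m /= m.sum(axis=1, keepdims=True)
            v = stationary_distribution(m)
            w, vec = np.linalg.eig(m.T)
            lead = vec[:, np.argmax(w.real)].real
            lead /= lead.sum()
            assert np.allclose(v, lead, atol=1e-9)


class TestSimilarity:
    def test_fixed_point_is_one(self):
        fp = Attractor((5,))
        assert attractor_similarity_exact(fp, 4) == 1.0
        assert attractor_similarity_approx(fp, 4) == 1.0

    def test_swap_cycle_exact_zero(self):
        # {(1,0),(0,1)}: both positions discordant across the two states
        cyc = Attractor((1, 2))
        assert attractor_similarity_exact(cyc, 2) == 0.0
        assert attractor_similarity_approx(cyc, 2) == 0.5

    def test_half_concordant_two_cycle(self):
        # {(0,0),(0,1)} with N=2: node 0 always 0, node 1 differs
        cyc = Attractor((0, 2))
        assert attractor_similarity_exact(cyc, 2) == 0.5
        assert attractor_similarity_approx(cyc, 2) == 0.75

    def test_landscape_means(self, swap_net):
        L = enumerate_landscape(swap_net)
        assert landscape_similarity(L, "exact") == pytest.approx(2 / 3)
        assert landscape_similarity(L, "approx") == pytest.approx(5 / 6)

    def test_all_fixed_point_landscape(self):
        L = enumerate_landscape(constant_zero_net(4))
        assert landscape_similarity(L, "exact") == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_approx_at_least_half_and_in_range(self, seed):
        a = random_state_attractor(50, 12, seed)
        assert attractor_similarity_approx(a, 12) >= 0.5
        assert 0.0 <= attractor_similarity_exact(a, 12) <= 1.0

    def test_exact_converges_to_approx_with_length(self):
        # pair-count and frequency-squared forms differ by O(1/l)
        gaps = []
        for length in (10, 100, 1000):
            a = random_state_attractor(length, 20, seed=7)
            gaps.append(
                abs(
                    attractor_similarity_exact(a, 20)
                    - attractor_similarity_approx(a, 20)
                )
            )
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-3


class TestEntropy:
    def test_uniform_is_maximal(self):
        assert normalized_entropy([0.25] * 4) == pytest.approx(1.0)

    def test_localized_is_zero(self):
        assert normalized_entropy([1.0, 0.0, 0.0]) == 0.0

    def test_three_outcome_value(self):
        assert normalized_entropy([0.25, 0.25, 0.5]) == pytest.approx(
            1.5 / np.log2(3)
        )

    def test_single_outcome_convention(self):
        assert normalized_entropy([1.0]) == 0.0

    def test_invalid_distributions_rejected(self):
        with pytest.raises(ValueError):
            normalized_entropy([0.5, 0.6])
        with pytest.raises(ValueError):
            normalized_entropy([1.5, -0.5])

    @given(st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=2, max_size=8))
    def test_permutation_invariance(self, weights):
        p = np.asarray(weights) / np.sum(weights)
        h = normalized_entropy(p)
        assert 0.0 <= h <= 1.0 + 1e-12
        assert normalized_entropy(p[::-1]) == pytest.approx(h, abs=1e-12)


class TestEntropyDifference:
    def test_identical_distributions(self):
        assert entropy_difference([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_localized_dynamics_positive(self):
        # noise concentrates on one attractor while basins are spread
        assert entropy_difference([1.0, 0.0], [0.5, 0.5]) == pytest.approx(1.0)

    def test_sign_convention(self):
        assert entropy_difference([0.5, 0.5], [1.0, 0.0]) == pytest.approx(-1.0)
        assert entropy_difference(
            [0.5, 0.5], [1.0, 0.0], convention="signed_terms"
        ) == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            entropy_difference([1.0], [0.5, 0.5])


class TestTransitionBias:
    def test_baseline_ratio_is_one(self):
        for seed in range(10):
            net = random_regular_network(10, 2, 0.4, seed)
            L = enumerate_landscape(net)
            if L.n_att < 2 or np.unique(L.basin_sizes).size < 2:
                continue
            bias = transition_bias(global_randomization_matrix(L), L.basin_sizes)
            assert bias.ratio == pytest.approx(1.0, abs=1e-12)

    def test_swap_net_hand_value(self, swap_net):
        L = enumerate_landscape(swap_net)
        M = build_transition_matrix(swap_net, L)
        bias = transition_bias(M, L.basin_sizes)
        assert bias.r_gt == pytest.approx(2.0)
        assert bias.r_lt == pytest.approx(2.0)
        assert bias.ratio == pytest.approx(1.0)

    def test_single_attractor_undefined(self):
        L = enumerate_landscape(constant_zero_net(3))
        bias = transition_bias(global_randomization_matrix(L), L.basin_sizes)
        assert bias == (None, None, None)

    def test_equal_basins_undefined(self):
        m = np.array([[0.2, 0.8], [0.7, 0.3]])
        assert transition_bias(m, [0.5, 0.5]) == (None, None, None)

    def test_source_normalization_switch(self):
        m = np.array([[0.5, 0.5], [0.25, 0.75]])
        b = np.array([0.25, 0.75])
        t = transition_bias(m, b, normalization="target")
        s = transition_bias(m, b, normalization="source")
        assert t.r_gt == pytest.approx(0.5 / 0.75)
        assert t.r_lt == pytest.approx(0.25 / 0.25)
        assert s.r_gt == pytest.approx(0.5 / 0.25)
        assert s.r_lt == pytest.approx(0.25 / 0.75)


class TestBuildReport:
    def test_swap_net_composition(self, swap_net):
        L = enumerate_landscape(swap_net)
        M = build_transition_matrix(swap_net, L)
        rep = build_report(swap_net, L, M)
        assert rep.trace == 0.0
        assert np.allclose(rep.stationary, [0.25, 0.5, 0.25])
        assert rep.similarity_exact == pytest.approx(2 / 3)
        assert rep.mean_stability == 0.0
        assert rep.n_att == 3

    def test_constant_net_fully_localized(self):
        net = constant_zero_net(4)
        L = enumerate_landscape(net)
        rep = build_report(net, L, build_transition_matrix(net, L))
        assert rep.trace == 1.0
        assert rep.stationary.tolist() == [1.0]
        assert rep.entropy == 0.0
        assert rep.bias_ratio is None

    @pytest.mark.parametrize("seed", range(5))
    def test_stationary_sums_to_one(self, seed):
        net = random_regular_network(10, 3, 0.35, seed)
        L = enumerate_landscape(net)
        rep = build_report(net, L, build_transition_matrix(net, L))
        assert rep.stationary.sum() == pytest.approx(1.0, abs=1e-10)
        assert 0.0 <= rep.entropy <= 1.0
        assert 0.0 <= rep.entropy_basin <= 1.0
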