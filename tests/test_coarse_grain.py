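"""Coherence, optimal cuts, eigenvector transforms, kinetic map, hierarchy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from conftest import block_chain, block_labels
from ethoscale import (TransitionMatrix, build_hierarchy, coherence, kinetic_map,
                       q_way_cut, reversibilize, spectrum, transform_eigvector,
                       two_way_cut)
from ethoscale.coarse_grain import block_ordered_view


def _nested_chain(eps_super=0.02, eps_sub=0.1, size=4):
    """Product chain: a slow 2-state factor (superblocks, leak eps_super), a
    faster 2-state factor (subblocks, leak eps_sub), and uniform mixing over
    ``size`` states within each of the 4 blocks.  Both slow eigenvectors are
    global contrasts, so log2(4) = 2 modes resolve all four blocks."""
    flip = lambda e: np.array([[1 - e, e], [e, 1 - e]])
    within = np.full((size, size), 1.0 / size)
    return np.kron(np.kron(flip(eps_super), flip(eps_sub)), within)


class TestCoherence:
    def test_identity_is_fully_coherent(self):
        assert coherence(np.eye(4), np.full(4, 0.25), [0, 2]) == 1.0

    def test_uniform_two_state(self):
        assert coherence(np.full((2, 2), 0.5), np.full(2, 0.5), [0]) == 0.5

    def test_two_block_leak(self):
        P = block_chain(10, eps=0.07)
        T = TransitionMatrix.from_P(P)
        assert coherence(T, S=np.arange(5)) == pytest.approx(1 - 0.07, abs=1e-10)

    def test_zero_mass_set_rejected(self):
        with pytest.raises(ValueError):
            coherence(np.eye(2), np.array([1.0, 0.0]), [1])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_bounded_on_random_chains(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.random((6, 6)) + 1e-3
        P /= P.sum(axis=1, keepdims=True)
        T = TransitionMatrix.from_P(P)
        S = rng.choice(6, size=rng.integers(1, 6), replace=False)
        assert 0.0 <= coherence(T, S=S) <= 1.0 + 1e-12


class TestTwoWayCut:
    def _cut(self, P):
        T = reversibilize(TransitionMatrix.from_P(P))
        modes = spectrum(T)
        return two_way_cut(modes.phis[:, 1], T.P, T.pi)

    def test_perfect_blocks_give_unit_coherence(self):
        P = block_chain(8, eps=0.0)
        phi_c, Sp, Sm, chi = self._cut(P)
        assert chi == pytest.approx(1.0, abs=1e-12)
        assert {frozenset(Sp.tolist()), frozenset(Sm.tolist())} == \
            {frozenset(range(4)), frozenset(range(4, 8))}

    def test_planted_blocks_recovered_with_expected_coherence(self):
        P = block_chain(10, eps=0.05)
        phi_c, Sp, Sm, chi = self._cut(P)
        assert chi == pytest.approx(0.95, abs=1e-10)
        assert {frozenset(Sp.tolist()), frozenset(Sm.tolist())} == \
            {frozenset(range(5)), frozenset(range(5, 10))}

    def test_rapidly_mixing_chain_has_low_coherence(self):
        # brute force over all thresholds of phi1 on a single fast block
        rng = np.random.default_rng(3)
        P = rng.random((8, 8)) + 1.0  # near-uniform: no metastability
        P /= P.sum(axis=1, keepdims=True)
        T = reversibilize(TransitionMatrix.from_P(P))
        modes = spectrum(T)
        phi = modes.phis[:, 1]
        _, _, _, chi = two_way_cut(phi, T.P, T.pi)
        best = 0.0
        order = np.argsort(phi)
        for k in range(1, 8):
            Sm, Sp = order[:k], order[k:]
            best = max(best, min(coherence(T, S=Sm), coherence(T, S=Sp)))
        assert chi == pytest.approx(best, abs=1e-12)
        assert chi < 0.7

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            two_way_cut(np.ones(4), np.eye(4), np.full(4, 0.25))


class TestTransformEigvector:
    def test_rank_spacing_example(self):
        out = transform_eigvector(np.array([-2.0, -1.0, 1.0, 2.0]), 0.0)
        np.testing.assert_allclose(out, [-1.0, -0.5, 0.5, 1.0])

    def test_single_negative_maps_to_minus_one(self):
        out = transform_eigvector(np.array([-3.0, 1.0, 2.0, 5.0]), 0.0)
        assert out[0] == -1.0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        phi = rng.standard_normal(12)
        a = transform_eigvector(phi, float(np.median(phi)))
        g = np.exp(phi) + 3 * phi  # strictly increasing map
        b = transform_eigvector(g, float(np.exp(np.median(phi)) + 3 * np.median(phi)))
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestKineticMap:
    def test_scale_factor_closed_form(self):
        psi = kinetic_map(np.ones(4), np.exp(-1.0), tau_star=3)
        np.testing.assert_allclose(psi, 1.5)

    def test_lambda_near_one_capped(self):
        psi = kinetic_map(np.ones((4, 2)), np.array([1 - 1e-16, 0.5]), tau_star=1)
        scale_fast = -1 / (2 * np.log(0.5))
        assert np.all(psi[:, 0] <= 10 * scale_fast + 1e-9)

    def test_slower_mode_weighs_more(self):
        psi = kinetic_map(np.ones((3, 2)), np.array([0.9, 0.5]), tau_star=1)
        assert psi[0, 0] > psi[0, 1]

    def test_sqrt_variant(self):
        lin = kinetic_map(np.ones(2), 0.5, tau_star=2, variant="linear")
        sq = kinetic_map(np.ones(2), 0.5, tau_star=2, variant="sqrt")
        np.testing.assert_allclose(sq, np.sqrt(lin))


class TestQWayCut:
    def test_four_planted_blocks_recovered(self):
        P = block_chain(16, eps=0.05, n_blocks=4)
        hierarchy = build_hierarchy(TransitionMatrix.from_P(P, tau=1), tau_star=1,
                                    q_list=[4])
        truth = block_labels(16, 4)
        assert adjusted_rand_score(truth, hierarchy[4].assignment) == 1.0

    def test_q2_matches_threshold_cut(self):
        P = block_chain(10, eps=0.1)
        T = reversibilize(TransitionMatrix.from_P(P))
        modes = spectrum(T)
        phi_c, Sp, Sm, _ = two_way_cut(modes.phis[:, 1], T.P, T.pi)
        hierarchy = build_hierarchy(TransitionMatrix.from_P(P, tau=1), tau_star=1,
                                    q_list=[2])
        cg = hierarchy[2]
        side = np.zeros(10, dtype=int)
        side[Sm] = 1
        assert adjusted_rand_score(side, cg.assignment) == 1.0

    def test_duplicate_rows_co_assigned(self):
        psi = np.array([[0.5, 0.1]] * 3 + [[-0.5, -0.2]] * 3 + [[0.9, 0.8]] * 2)
        cg = q_way_cut(psi, np.full(8, 1 / 8), q=3, seed=0)
        for block in (slice(0, 3), slice(3, 6), slice(6, 8)):
            assert len(np.unique(cg.assignment[block])) == 1

    def test_invalid_q(self):
        with pytest.raises(ValueError):
            q_way_cut(np.zeros((4, 1)), np.full(4, 0.25), q=5)


class TestHierarchy:
    def test_nested_planting_recovered_in_order(self):
        P = _nested_chain()
        hierarchy = build_hierarchy(TransitionMatrix.from_P(P, tau=1), tau_star=1,
                                    q_list=[2, 4])
        super_truth = np.repeat([0, 1], 8)  # slow factor: first Kronecker index
        sub_truth = np.repeat([0, 1, 2, 3], 4)
        assert adjusted_rand_score(super_truth, hierarchy[2].assignment) == 1.0
        assert adjusted_rand_score(sub_truth, hierarchy[4].assignment) == 1.0

    def test_strategies_beat_random_equal_mass_sets(self):
        P = block_chain(12, eps=0.05, n_blocks=2)
        T = TransitionMatrix.from_P(P, tau=1)
        hierarchy = build_hierarchy(T, tau_star=1, q_list=[2])
        cg = hierarchy[2]
        rng = np.random.default_rng(0)
        null = []
        for _ in range(200):
            S = rng.choice(12, size=6, replace=False)
            null.append(coherence(T, S=S))
        assert cg.strategy_coherence.min() >= np.percentile(null, 99)

    def test_q2_masses_partition_unity(self):
        P = block_chain(8, eps=0.1)
        T = TransitionMatrix.from_P(P, tau=1)
        hierarchy = build_hierarchy(T, tau_star=1, q_list=[2])
        masses = [T.pi[hierarchy[2].assignment == s].sum() for s in (0, 1)]
        assert sum(masses) == pytest.approx(1.0, abs=1e-10)

    def test_block_ordered_view_is_permutation(self):
        P = block_chain(8, eps=0.1)
        T = TransitionMatrix.from_P(P, tau=1)
        cg = build_hierarchy(T, tau_star=1, q_list=[2])[2]
        perm, Pb = block_ordered_view(T, cg.assignment)
        assert sorted(perm.tolist()) == list(range(8))
        np.testing.assert_allclose(Pb.sum(axis=1), 1.0)
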