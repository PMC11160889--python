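"""Transition-matrix metric, CSE, significance scales, classifier, HMD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from ethoscale import (FishModel, classify_contexts, cse_embed, distance_matrix,
                       fit_fish, fuzzy_cmeans_1d, generate_strategy_sequence,
                       hmd_cluster, significance_scale, tm_distance)
from ethoscale.phenotype import PhenotypeSpace


def _random_stochastic(rng, q):
    T = rng.random((q, q)) + 1e-3
    return T / T.sum(axis=1, keepdims=True)


def _models_from_chains(chains, length, base_seed=0, contexts=None):
    models = []
    for i, chain in enumerate(chains):
        seq = generate_strategy_sequence(chain, length, seed=base_seed + i)
        m = fit_fish(seq, q=chain.shape[0], fish_id=f"f{i}",
                     context=(contexts[i] if contexts else "default"))
        models.append(m)
    return models


class TestTmDistance:
    def test_identity_of_indiscernibles(self):
        T = np.array([[0.7, 0.3], [0.4, 0.6]])
        assert tm_distance(T, T) == 0.0

    def test_permuted_two_state_worked_value(self):
        assert tm_distance(np.eye(2), np.array([[0.0, 1.0], [1.0, 0.0]])) == 2.0

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            A, B, C = (_random_stochastic(rng, 3) for _ in range(3))
            dab, dba = tm_distance(A, B), tm_distance(B, A)
            assert abs(dab - dba) < 1e-12
            assert dab >= 0
            assert tm_distance(A, C) <= dab + tm_distance(B, C) + 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            tm_distance(np.eye(2), np.eye(3))


class TestDistanceMatrix:
    def test_identical_cohort_zero_matrix(self):
        T = np.array([[0.8, 0.2], [0.3, 0.7]])
        models = [FishModel(f"f{i}", 2, T, 100, 0) for i in range(4)]
        space = distance_matrix(models)
        np.testing.assert_allclose(space.D, 0.0)

    def test_planted_groups_separate(self):
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        B = np.array([[0.5, 0.5], [0.5, 0.5]])
        d0 = tm_distance(A, B)
        models = _models_from_chains([A] * 5 + [B] * 5, length=20_000)
        D = distance_matrix(models).D
        within = np.concatenate([D[:5, :5][np.triu_indices(5, 1)],
                                 D[5:, 5:][np.triu_indices(5, 1)]])
        between = D[:5, 5:].ravel()
        assert within.mean() < 0.05
        assert abs(between.mean() - d0) < 0.05

    def test_permutation_consistency(self):
        rng = np.random.default_rng(1)
        models = [FishModel(f"f{i}", 2, _random_stochastic(rng, 2), 100, 0)
                  for i in range(5)]
        D = distance_matrix(models).D
        perm = [3, 1, 4, 0, 2]
        D2 = distance_matrix([models[i] for i in perm]).D
        np.testing.assert_allclose(D2, D[np.ix_(perm, perm)])


class TestCSE:
    def test_collinear_points_reconstructed_unshifted(self):
        x = np.array([0.0, 1.0, 2.0, 5.0, 9.0])[:, None]
        D = squareform(pdist(x))
        coords, w = cse_embed(D)
        demb = squareform(pdist(coords)) ** 2
        off = ~np.eye(5, dtype=bool)
        assert np.sqrt(np.mean((demb - D)[off] ** 2)) < 1e-8

    def test_two_points_separation(self):
        coords, _ = cse_embed(np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert coords.shape[1] == 1
        assert np.linalg.norm(coords[0] - coords[1]) ** 2 == pytest.approx(3.0)

    def test_shift_makes_weights_nonnegative(self):
        rng = np.random.default_rng(2)
        A = rng.random((8, 8))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0.0)
        _, w = cse_embed(D)
        assert w.min() >= -1e-10

    def test_shifted_dissimilarities_reproduced_exactly(self):
        rng = np.random.default_rng(3)
        A = rng.random((7, 7))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0.0)
        coords, w = cse_embed(D, tol=-np.inf)  # keep every dimension
        demb = squareform(pdist(coords)) ** 2
        n = 7
        Q = np.eye(n) - 1 / n
        S = -0.5 * Q @ D @ Q
        lam_min = min(np.linalg.eigvalsh(S).min(), 0.0)
        off = ~np.eye(n, dtype=bool)
        np.testing.assert_allclose(demb[off], (D - 2 * lam_min)[off], atol=1e-8)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            cse_embed(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestSignificanceScale:
    def test_identity_model_has_zero_eps(self):
        m = FishModel("f", 2, np.eye(2), 500, start_state=0)
        assert significance_scale(m, n_sims=10, seed=0) == 0.0

    def test_eps_decreases_with_length(self):
        T = np.array([[0.8, 0.2], [0.3, 0.7]])
        m = FishModel("f", 2, T, 100, start_state=0)
        eps = [significance_scale(m, n_sims=50, seed=1, length=n)
               for n in (100, 1000, 10_000)]
        assert eps[0] > eps[1] > eps[2]

    def test_clt_scaling_exponent(self):
        T = np.array([[0.7, 0.3], [0.4, 0.6]])
        m = FishModel("f", 2, T, 100, start_state=0)
        lengths = np.array([100, 1000, 10_000])
        eps = np.array([significance_scale(m, n_sims=100, seed=2, length=int(n))
                        for n in lengths])
        slope = np.polyfit(np.log(lengths), np.log(eps), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)


class TestFuzzyCMeans:
    def test_two_point_memberships_closed_form(self):
        # point at distance d1, d2 from the two centers: u1 = 1/(1+(d1/d2)^2)
        x = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0, 2.0])
        u, centers = fuzzy_cmeans_1d(x, c=2, m=2.0, seed=0)
        np.testing.assert_allclose(centers, [0.0, 10.0], atol=0.6)
        d1, d2 = abs(2.0 - centers[0]), abs(2.0 - centers[1])
        expect = 1.0 / (1.0 + (d1 / d2) ** 2)
        assert u[6, 0] == pytest.approx(expect, abs=0.01)

    def test_memberships_sum_to_one(self):
        rng = np.random.default_rng(4)
        u, _ = fuzzy_cmeans_1d(rng.standard_normal(50), c=2, seed=0)
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-9)


class TestClassifier:
    def _space_and_labels(self, d0_chains, n_per=20, length=2000, seed=0):
        chains, contexts = [], []
        for ci, chain in enumerate(d0_chains):
            chains += [chain] * n_per
            contexts += [f"ctx{ci}"] * n_per
        models = _models_from_chains(chains, length, base_seed=seed,
                                     contexts=contexts)
        space = distance_matrix(models)
        return space, contexts

    def test_separable_contexts_classified(self):
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        B = np.array([[0.4, 0.6], [0.6, 0.4]])
        space, labels = self._space_and_labels([A, B])
        res = classify_contexts(space, labels, n_shuffles=20, seed=0)
        assert res["test_accuracy"].mean() > 0.9

    def test_single_generator_contexts_at_chance(self):
        A = np.array([[0.7, 0.3], [0.3, 0.7]])
        space, labels = self._space_and_labels([A, A])
        res = classify_contexts(space, labels, n_shuffles=20, seed=1)
        acc = res["test_accuracy"]
        se = np.sqrt(0.25 / (len(acc) * 8))  # pooled binomial s.e. at chance
        assert abs(acc.mean() - 0.5) <= 3 * max(se, acc.std() / np.sqrt(len(acc)))

    def test_train_accuracy_dominates_test(self):
        A = np.array([[0.85, 0.15], [0.2, 0.8]])
        B = np.array([[0.6, 0.4], [0.45, 0.55]])
        space, labels = self._space_and_labels([A, B], length=300)
        res = classify_contexts(space, labels, n_shuffles=20, seed=2)
        assert res["train_accuracy"].mean() >= res["test_accuracy"].mean()


class TestHMD:
    def _planted_space(self, chains_by_group, n_per, length, seed):
        chains, groups = [], []
        for g, chain in enumerate(chains_by_group):
            chains += [chain] * n_per
            groups += [g] * n_per
        models = _models_from_chains(chains, length, base_seed=seed)
        space = distance_matrix(models)
        eps = np.array([significance_scale(m, n_sims=30, seed=seed + i)
                        for i, m in enumerate(models)])
        return space.D, np.clip(eps, 1e-6, None), np.array(groups)

    def test_two_planted_groups_recovered(self):
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        B = np.array([[0.4, 0.6], [0.6, 0.4]])
        aris = []
        for seed in range(20):
            D, eps, truth = self._planted_space([A, B], n_per=10, length=3000,
                                                seed=100 * seed)
            tree = hmd_cluster(D, eps, max_levels=1, seed=seed)
            aris.append(adjusted_rand_score(truth, tree.hard_labels(0)))
        assert np.mean(aris) > 0.95

    def test_null_cohort_has_no_confident_split(self):
        # across null cohorts the typical fish stays unconfident at level 1
        A = np.array([[0.7, 0.3], [0.3, 0.7]])
        fracs = []
        for seed in range(10):
            D, eps, _ = self._planted_space([A, A], n_per=10, length=2000,
                                            seed=1000 * seed + 7)
            tree = hmd_cluster(D, eps, max_levels=3, seed=0)
            top = tree.posteriors[0].max(axis=1)
            fracs.append(np.mean(top < 0.7))
        assert np.mean(fracs) >= 0.5

    def test_nested_split_order_follows_scale(self):
        base = lambda a, b: np.array([[a, 1 - a], [1 - b, b]])
        # two superpairs far apart; members of a pair moderately apart
        chains = [base(0.9, 0.9), base(0.8, 0.8), base(0.2, 0.2), base(0.3, 0.3)]
        D, eps, truth = self._planted_space(chains, n_per=6, length=4000, seed=11)
        tree = hmd_cluster(D, eps, max_levels=3, stop_rel_gain=-np.inf, seed=0)
        superpair = (truth >= 2).astype(int)
        assert adjusted_rand_score(superpair, tree.hard_labels(0)) == 1.0
        if tree.n_levels >= 3:
            assert adjusted_rand_score(truth, tree.hard_labels(2)) > 0.9

    def test_invariance_to_joint_rescaling(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((12, 2))
        D = squareform(pdist(X))
        eps = rng.random(12) + 0.5
        t1 = hmd_cluster(D, eps, max_levels=2, seed=0)
        t2 = hmd_cluster(7.3 * D, 7.3 * eps, max_levels=2, seed=0)
        np.testing.assert_allclose(t1.posteriors[-1], t2.posteriors[-1], atol=1e-8)

    def test_recovery_degrades_gracefully(self):
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        seps = [0.5, 0.2, 0.05, 0.01]
        aris = []
        for sep in seps:
            B = np.array([[0.9 - sep, 0.1 + sep], [0.1 + sep, 0.9 - sep]])
            vals = []
            for seed in range(5):
                D, eps, truth = self._planted_space([A, B], n_per=8, length=300,
                                                    seed=1000 + 50 * seed)
                tree = hmd_cluster(D, eps, max_levels=1, seed=seed)
                vals.append(adjusted_rand_score(truth, tree.hard_labels(0)))
            aris.append(np.mean(vals))
        assert aris[0] > aris[-1]

    def test_small_cluster_never_split(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        tree = hmd_cluster(D, np.array([0.1, 0.1]), max_levels=2, seed=0)
        assert tree.n_levels == 0
        assert tree.stopped_reason == "no splittable cluster"

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 1000))
    def test_posteriors_sum_to_one_per_level(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((10, 2))
        D = squareform(pdist(X))
        eps = rng.random(10) + 0.2
        tree = hmd_cluster(D, eps, max_levels=3, stop_rel_gain=-np.inf, seed=0)
        for post in tree.posteriors:
            np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-8)
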