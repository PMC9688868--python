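"""Consensus clustering machinery: scaling, distances, PAM, consensus
matrices, optimal-k rule, IGP and PCA."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from radsubtype.cluster import (ConsensusResult, compute_centroids,
                                consensus_cluster, final_labels,
                                igp_validate, pam_cluster,
                                pca_contributions, select_optimal_k,
                                spearman_distance, zscore_features)

import oracles


class TestZscore:
    def test_basic_column(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 10.0]})
        scaled, scaling = zscore_features(table)
        assert np.allclose(scaled["a"], [-1.0, 0.0, 1.0])  # sample sd
        assert scaling.loc["a", "sd"] == pytest.approx(1.0)

    def test_constant_column_dropped_with_warning(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            scaled, _ = zscore_features(table)
        assert list(scaled.columns) == ["a"]

    def test_affine_invariance(self, rng):
        table = pd.DataFrame(rng.uniform(size=(10, 4)))
        s1, _ = zscore_features(table)
        s2, _ = zscore_features(table * 10.0 + 3.0)
        assert np.allclose(s1, s2)

    def test_all_constant_errors(self):
        with pytest.raises(ValueError):
            zscore_features(pd.DataFrame({"a": [1.0, 1.0]}))


class TestSpearmanDistance:
    def test_identical_and_reversed_profiles(self):
        X = np.array([[1.0, 2.0, 3.0, 4.0],
                      [10.0, 20.0, 30.0, 40.0],
                      [4.0, 3.0, 2.0, 1.0]])
        D = spearman_distance(X)
        assert D[0, 1] == pytest.approx(0.0)
        assert D[0, 2] == pytest.approx(2.0)
        assert np.allclose(np.diag(D), 0.0)

    def test_matches_rank_pearson_oracle(self, rng):
        X = rng.uniform(size=(6, 20))
        D = spearman_distance(X)
        for i in range(6):
            for j in range(6):
                rho = oracles.spearman_oracle(X[i], X[j])
                assert D[i, j] == pytest.approx(1.0 - rho, abs=1e-9)

    def test_constant_profile_flagged(self):
        X = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning, match="constant"):
            D = spearman_distance(X)
        assert D[0, 1] == pytest.approx(1.0)
        assert D[0, 0] == 0.0


def euclidean_distance(X):
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff ** 2).sum(-1))


class TestPAM:
    def test_two_separated_pairs(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels, medoids = pam_cluster(euclidean_distance(X), 2)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_k_equals_n_zero_cost(self):
        D = euclidean_distance(np.arange(5.0)[:, None])
        labels, medoids = pam_cluster(D, 5)
        assert sorted(medoids) == list(range(5))
        assert oracles.pam_cost(D, labels, medoids) == 0.0

    def test_deterministic(self, rng):
        D = euclidean_distance(rng.uniform(size=(12, 3)))
        out1 = pam_cluster(D, 3)
        out2 = pam_cluster(D, 3)
        assert np.array_equal(out1[0], out2[0])
        assert np.array_equal(out1[1], out2[1])

    def test_near_optimal_vs_exhaustive(self, rng):
        """BUILD+SWAP should hit the exhaustive-search optimum on
        nearly every small random instance."""
        hits = 0
        trials = 40
        for _ in range(trials):
            n = int(rng.integers(5, 9))
            k = int(rng.integers(2, 4))
            D = euclidean_distance(rng.uniform(size=(n, 3)))
            labels, medoids = pam_cluster(D, k)
            cost = oracles.pam_cost(D, labels, medoids)
            best = oracles.pam_exhaustive_cost(D, k)
            if cost <= best + 1e-9:
                hits += 1
        assert hits / trials >= 0.95

    def test_bad_k_errors(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError):
            pam_cluster(D, 4)


class TestConsensus:
    def test_two_point_masses(self, rng):
        # two sharply distinct feature *profiles* (Spearman distance
        # sees rank patterns, not locations) with tiny noise
        base_a = rng.uniform(size=10)
        base_b = rng.uniform(size=10)
        X = np.vstack([base_a + rng.normal(0, 1e-3, (6, 10)),
                       base_b + rng.normal(0, 1e-3, (6, 10))])
        table = pd.DataFrame(X)
        res = consensus_cluster(table, k_range=(2, 3), reps=50, seed=0)
        M = res.consensus[2]
        within = np.r_[M[:6, :6][np.triu_indices(6, 1)],
                       M[6:, 6:][np.triu_indices(6, 1)]]
        across = M[:6, 6:].ravel()
        assert within.min() > 0.99
        assert across.max() < 0.01

    def test_matrix_contract(self, small_scaled):
        scaled, _ = small_scaled
        res = consensus_cluster(scaled, k_range=(2, 3, 4), reps=40, seed=7)
        for M in res.consensus.values():
            assert np.allclose(M, M.T)
            assert np.allclose(np.diag(M), 1.0)
            assert M.min() >= 0.0 and M.max() <= 1.0

    def test_seed_determinism(self, small_scaled):
        scaled, _ = small_scaled
        r1 = consensus_cluster(scaled, k_range=(2, 3), reps=30, seed=3)
        r2 = consensus_cluster(scaled, k_range=(2, 3), reps=30, seed=3)
        assert np.array_equal(r1.labels, r2.labels)
        for k in (2, 3):
            assert np.array_equal(r1.consensus[k], r2.consensus[k])

    def test_planted_structure_separates(self, small_cohort, small_scaled):
        scaled, _ = small_scaled
        res = consensus_cluster(scaled, k_range=(2, 3, 4), reps=100, seed=1)
        truth = small_cohort.truth_labels
        M = res.consensus[3]
        same = truth[:, None] == truth[None, :]
        iu = np.triu_indices(len(truth), 1)
        within = M[iu][same[iu]].mean()
        between = M[iu][~same[iu]].mean()
        assert within > between

    def test_reps_validation(self, small_scaled):
        with pytest.raises(ValueError):
            consensus_cluster(small_scaled[0], reps=0)


def make_result(deltas):
    ks = tuple(sorted(deltas))
    return ConsensusResult(ks, {}, {}, dict(deltas), ks[0],
                           np.zeros(1, dtype=int), ["s"])


class TestOptimalK:
    def test_elbow_after_true_k(self):
        res = make_result({2: 0.45, 3: 0.40, 4: 0.05, 5: 0.02})
        assert select_optimal_k(res, threshold=0.10) == 3

    def test_all_above_threshold_flags_max(self):
        res = make_result({2: 0.5, 3: 0.4, 4: 0.3})
        assert select_optimal_k(res, threshold=0.10) == 4
        assert any("every tested k" in f for f in res.flags)

    def test_none_above_threshold_flags_min(self):
        res = make_result({2: 0.01, 3: 0.005})
        assert select_optimal_k(res, threshold=0.10) == 2
        assert any("falling back" in f for f in res.flags)


class TestFinalLabels:
    def test_block_diagonal_recovered(self):
        M = np.zeros((9, 9))
        for block in (slice(0, 3), slice(3, 6), slice(6, 9)):
            M[block, block] = 1.0
        labels = final_labels(M, 3)
        assert len(set(labels[:3])) == 1
        assert len({labels[0], labels[3], labels[6]}) == 3

    def test_permutation_equivariant(self, rng):
        M = np.zeros((8, 8))
        M[:4, :4] = 1.0
        M[4:, 4:] = 1.0
        perm = rng.permutation(8)
        lab = final_labels(M, 2)
        lab_p = final_labels(M[np.ix_(perm, perm)], 2)
        assert adjusted_rand_score(lab[perm], lab_p) == 1.0

    def test_noisy_blocks(self, rng):
        truth = np.repeat([0, 1, 2], 10)
        M = (truth[:, None] == truth[None, :]).astype(float)
        noise = rng.normal(0, 0.1, M.shape)
        M = np.clip((M + noise + (M + noise).T) / 2, 0, 1)
        np.fill_diagonal(M, 1.0)
        labels = final_labels(M, 3)
        assert adjusted_rand_score(truth, labels) >= 0.9


class TestCentroidsAndIGP:
    def test_centroids_are_group_means(self, rng):
        scaled = pd.DataFrame(rng.uniform(size=(10, 5)))
        labels = rng.integers(0, 3, 10)
        scaling = pd.DataFrame({"mean": np.zeros(5), "sd": np.ones(5)})
        model = compute_centroids(scaled, labels, scaling)
        for g in np.unique(labels):
            expected = scaled[labels == g].mean(axis=0)
            assert np.allclose(model.centroids.loc[g], expected)

    def test_singleton_cluster_centroid_is_the_sample(self, rng):
        scaled = pd.DataFrame(rng.uniform(size=(4, 6)))
        labels = np.array([0, 1, 1, 1])
        scaling = pd.DataFrame({"mean": np.zeros(6), "sd": np.ones(6)})
        model = compute_centroids(scaled, labels, scaling)
        assert np.allclose(model.centroids.loc[0], scaled.iloc[0])

    def test_igp_chance_level_for_random_labels(self, rng):
        """Labels drawn uniformly over 3 groups on unstructured data:
        the mean in-group proportion sits at the ~33% chance level."""
        from radsubtype.cluster import igp_from_labels
        igps = []
        for _ in range(20):
            profiles = rng.standard_normal((60, 30))
            labels = rng.choice(["a", "b", "c"], 60)
            igps.extend(igp_from_labels(profiles, labels).values())
        assert np.mean(igps) == pytest.approx(100.0 / 3.0, abs=5.0)

    def test_igp_missing_features_error(self, rng):
        from radsubtype.cluster import SubtypeModel
        model = SubtypeModel(
            centroids=pd.DataFrame(np.zeros((2, 3)),
                                   columns=["a", "b", "c"]),
            scaling=pd.DataFrame({"mean": np.zeros(3), "sd": np.ones(3)},
                                 index=["a", "b", "c"]))
        with pytest.raises(ValueError, match="lacks"):
            igp_validate(pd.DataFrame({"a": [1.0], "b": [2.0]}), model)


class TestPCA:
    def test_axis_aligned_components(self):
        # two independent features with very different variances: the
        # first component must align with the dominant axis
        rngl = np.random.default_rng(0)
        table = pd.DataFrame({"f1": 10 * rngl.standard_normal(200),
                              "f2": rngl.standard_normal(200)})
        loadings, evr, contrib = pca_contributions(table)
        assert abs(loadings.iloc[0]["f1"]) > 0.99
        assert evr[0] > 0.95

    def test_matches_eigendecomposition(self, rng):
        table = pd.DataFrame(rng.uniform(size=(30, 5)))
        scaled, _ = zscore_features(table)
        _, evr, _ = pca_contributions(scaled)
        X = np.asarray(scaled) - np.asarray(scaled).mean(0)
        eig = np.sort(np.linalg.eigvalsh(X.T @ X / (len(X) - 1)))[::-1]
        assert np.allclose(evr, eig / eig.sum(), atol=1e-9)
        assert evr.sum() == pytest.approx(1.0)
        contrib = pca_contributions(scaled)[2]
        assert np.allclose(contrib.sum(axis=1), 100.0)
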