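import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import leukotype as lt
from leukotype.consensus_subtyping import (
    ConsensusMatrix,
    PartitionEnsemble,
    _renumber_by_size,
)
from leukotype.core_io import CohortError
from leukotype.feature_selection import FeatureMatrix


def _blobs_fm(seed=0, n_per=20, k=3, sigma=0.1):
    """Well-separated Gaussian blobs as a FeatureMatrix."""
    rng = np.random.default_rng(seed)
    centers = np.eye(k) * 5
    X = np.vstack([
        rng.normal(centers[c], sigma, size=(n_per, k)) for c in range(k)
    ])
    truth = np.repeat(np.arange(1, k + 1), n_per)
    df = pd.DataFrame(
        X, index=[f"s{i}" for i in range(len(X))],
        columns=[f"f{j}" for j in range(k)],
    )
    return FeatureMatrix(continuous=df), truth


def _ensemble_from_labels(sample_ids, labelings, k):
    return PartitionEnsemble(
        k, list(sample_ids),
        [(f"p{i}", np.asarray(l)) for i, l in enumerate(labelings)], seed=0,
    )


class TestRunBasePartitions:
    def test_separated_clouds_pure_for_every_algorithm(self):
        fm, truth = _blobs_fm(k=2, n_per=15)
        ens = lt.run_base_partitions(fm, 2, seed=0)
        for name, labels in ens.partitions:
            assert adjusted_rand_score(truth, labels) == 1.0, name

    def test_same_seed_identical(self):
        fm, _ = _blobs_fm(k=3)
        a = lt.run_base_partitions(fm, 3, seed=5)
        b = lt.run_base_partitions(fm, 3, seed=5)
        for (_, la), (_, lb) in zip(a.partitions, b.partitions):
            np.testing.assert_array_equal(la, lb)

    def test_k2_on_three_blobs_uses_both_labels(self):
        fm, _ = _blobs_fm(k=3)
        ens = lt.run_base_partitions(fm, 2, seed=0)
        for name, labels in ens.partitions:
            assert set(labels) == {1, 2}, name

    def test_bad_inputs_rejected(self):
        fm, _ = _blobs_fm(k=2, n_per=3)
        with pytest.raises(CohortError):
            lt.run_base_partitions(fm, 99, seed=0)
        with pytest.raises(CohortError):
            lt.run_base_partitions(fm, 2, algorithms=("kmeans",), seed=0)
        with pytest.raises(CohortError):
            lt.run_base_partitions(fm, 2, algorithms=("kmeans", "nope"), seed=0)

    def test_snf_included_on_two_layers(self, feature_matrix_factory):
        fm, truth, _ = feature_matrix_factory(seed=4)
        ens = lt.run_base_partitions(fm, 3, algorithms=("kmeans", "snf"), seed=0)
        assert {n for n, _ in ens.partitions} == {"kmeans", "snf"}


class TestConsensusMatrix:
    def test_identical_partitions_give_binary_matrix(self):
        labels = [1, 1, 2, 2]
        ens = _ensemble_from_labels("abcd", [labels, labels], 2)
        M = lt.consensus_matrix(ens).M
        assert set(np.unique(M)) <= {0.0, 1.0}

    def test_half_agreement_gives_half_entries(self):
        ens = _ensemble_from_labels("abcd", [[1, 1, 2, 2], [1, 2, 1, 2]], 2)
        M = lt.consensus_matrix(ens).M
        assert M[0, 1] == 0.5 and M[0, 2] == 0.5

    def test_symmetric_unit_diagonal_invariant(self, feature_matrix_factory):
        fm, _, _ = feature_matrix_factory(seed=1)
        M = lt.consensus_matrix(lt.run_base_partitions(fm, 3, seed=1)).M
        np.testing.assert_allclose(M, M.T)
        np.testing.assert_allclose(np.diag(M), 1.0)

    def test_sample_reorder_permutes_matrix(self):
        ens = _ensemble_from_labels("abcd", [[1, 1, 2, 2], [1, 2, 1, 2]], 2)
        M = lt.consensus_matrix(ens).M
        perm = [2, 0, 3, 1]
        ens_p = _ensemble_from_labels(
            [list("abcd")[i] for i in perm],
            [[l[i] for i in perm] for l in [[1, 1, 2, 2], [1, 2, 1, 2]]], 2,
        )
        Mp = lt.consensus_matrix(ens_p).M
        np.testing.assert_allclose(Mp, M[np.ix_(perm, perm)])


def _brute_force_average_linkage(D: np.ndarray, k: int) -> list[set]:
    """Oracle: naive agglomerative average-linkage by direct recomputation."""
    clusters = [{i} for i in range(D.shape[0])]
    while len(clusters) > k:
        best, pair = np.inf, None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if d < best - 1e-12:
                best, pair = d, (a, b)
        a, b = pair
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return clusters


class TestConsensusLabels:
    def test_two_perfect_blocks_recovered(self):
        M = np.zeros((6, 6))
        M[:3, :3] = 1.0
        M[3:, 3:] = 1.0
        cm = ConsensusMatrix([f"s{i}" for i in range(6)], M)
        labels = lt.consensus_labels(cm, 2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_noisy_three_block_matrix_recovered(self):
        n = 12
        M = np.full((n, n), 0.1)
        for block in (slice(0, 4), slice(4, 8), slice(8, 12)):
            M[block, block] = 1.0
        np.fill_diagonal(M, 1.0)
        cm = ConsensusMatrix([f"s{i}" for i in range(n)], M)
        labels = lt.consensus_labels(cm, 3)
        truth = np.repeat([1, 2, 3], 4)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_identical_ensemble_reproduces_base_labels(self):
        base = [1, 2, 2, 3, 3, 3]
        ens = _ensemble_from_labels("abcdef", [base, base, base], 3)
        labels = lt.consensus_labels(lt.consensus_matrix(ens), 3)
        assert adjusted_rand_score(base, labels) == 1.0

    def test_matches_brute_force_small_instances(self):
        """Average-linkage cut equals exhaustive linkage recomputation."""
        rng = np.random.default_rng(7)
        for trial in range(5):
            n = rng.integers(5, 12)
            labels_true = rng.integers(0, 3, size=n)
            noise = rng.uniform(0, 0.2, size=(n, n))
            M = (labels_true[:, None] == labels_true[None, :]).astype(float)
            M = np.clip(M - noise, 0, 1)
            M = (M + M.T) / 2
            np.fill_diagonal(M, 1.0)
            k = len(np.unique(labels_true))
            cm = ConsensusMatrix([f"s{i}" for i in range(n)], M)
            got = lt.consensus_labels(cm, k)
            oracle = _brute_force_average_linkage(cm.distance(), k)
            oracle_labels = np.empty(n, dtype=int)
            for c, members in enumerate(oracle):
                for i in members:
                    oracle_labels[i] = c
            assert adjusted_rand_score(oracle_labels, got) == 1.0

    def test_duplicate_partition_does_not_change_labels(self):
        labelings = [[1, 1, 2, 2, 3, 3], [1, 1, 1, 2, 3, 3], [1, 2, 2, 2, 3, 3]]
        ens = _ensemble_from_labels("abcdef", labelings, 3)
        base = lt.consensus_labels(lt.consensus_matrix(ens), 3)
        ens_dup = _ensemble_from_labels("abcdef", labelings + [labelings[0]] * 1, 3)
        # duplicating a partition twice keeps pair ordering of distances
        ens_dup2 = _ensemble_from_labels(
            "abcdef", labelings + [labelings[0], labelings[0]], 3
        )
        for e in (ens_dup, ens_dup2):
            np.testing.assert_array_equal(
                base, lt.consensus_labels(lt.consensus_matrix(e), 3)
            )

    def test_k_beyond_distinct_profiles_rejected(self):
        M = np.ones((4, 4))
        cm = ConsensusMatrix(list("abcd"), M)
        with pytest.raises(CohortError, match="distinct consensus profiles"):
            lt.consensus_labels(cm, 2)

    def test_renumbering_by_size(self):
        labels = np.array([2, 2, 1, 2, 1, 2])
        out = _renumber_by_size(labels)
        assert list(out) == [1, 1, 2, 1, 2, 1]


class TestSilhouette:
    def test_perfect_separation_scores_one(self):
        D = np.ones((4, 4)) - np.eye(4)
        D[0, 1] = D[1, 0] = 0.0
        D[2, 3] = D[3, 2] = 0.0
        s, per_cluster, mean = lt.silhouette_scores(np.array([1, 1, 2, 2]), D)
        np.testing.assert_allclose(s, 1.0)

    def test_matches_hand_enumeration_four_points(self):
        # points on a line at 0, 1, 5, 6; clusters {0,1}, {5,6}
        pos = np.array([0.0, 1.0, 5.0, 6.0])
        D = np.abs(pos[:, None] - pos[None, :])
        labels = np.array([1, 1, 2, 2])
        s, _, _ = lt.silhouette_scores(labels, D)
        # hand: a(0)=1, b(0)=(5+6)/2=5.5 -> 4.5/5.5; a(1)=1, b(1)=4.5 -> 3.5/4.5
        expected = [4.5 / 5.5, 3.5 / 4.5, 3.5 / 4.5, 4.5 / 5.5]
        np.testing.assert_allclose(s, expected)

    def test_singleton_scores_zero(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        s, per_cluster, _ = lt.silhouette_scores(np.array([1, 2, 2]), D)
        assert s[0] == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(CohortError):
            lt.silhouette_scores(np.array([1, 1, 1]), np.zeros((3, 3)))


class TestGapStatistic:
    def test_three_blobs_peak_at_three(self):
        votes = []
        for seed in range(10):
            fm, _ = _blobs_fm(seed=seed, n_per=15, k=3, sigma=0.1)
            gap = lt.gap_statistic(fm, range(1, 6), B=50, seed=seed)
            votes.append(int(gap["gap"].idxmax()))
        assert np.median(votes) == 3

    def test_single_blob_prefers_one_cluster(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 2))
        df = pd.DataFrame(X, index=[f"s{i}" for i in range(50)])
        gap = lt.gap_statistic(FeatureMatrix(continuous=df), (1, 2), B=50, seed=0)
        # one-standard-error rule: Gap(1) >= Gap(2) - se(2)
        assert gap.loc[1, "gap"] >= gap.loc[2, "gap"] - gap.loc[2, "se"]

    def test_deterministic_given_seed(self):
        fm, _ = _blobs_fm(seed=1)
        a = lt.gap_statistic(fm, (2, 3), B=10, seed=4)
        b = lt.gap_statistic(fm, (2, 3), B=10, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_small_b_rejected(self):
        fm, _ = _blobs_fm()
        with pytest.raises(CohortError):
            lt.gap_statistic(fm, (2,), B=1, seed=0)


class TestCpi:
    def test_perfect_agreement_is_one(self):
        # pam's rank-correlation distance is not meaningful in a 3-feature
        # space, so the registry subset suited to blob geometry is used
        fm, _ = _blobs_fm(k=3, n_per=15)
        curve = lt.cpi(
            fm, (3,), algorithms=("kmeans", "ward", "spectral", "gmm", "nmf"),
            seed=0,
        )
        assert curve[3] == pytest.approx(1.0)

    def test_independent_partitions_near_zero(self):
        rng = np.random.default_rng(0)
        labelings = [rng.integers(1, 4, size=200) for _ in range(6)]
        aris = [
            adjusted_rand_score(a, b)
            for i, a in enumerate(labelings)
            for b in labelings[i + 1:]
        ]
        assert abs(np.mean(aris)) < 0.1

    def test_single_algorithm_rejected(self):
        fm, _ = _blobs_fm()
        with pytest.raises(CohortError):
            lt.cpi(fm, (2,), algorithms=("kmeans",), seed=0)


class TestFitSubtypes:
    def test_reproducible_given_seed(self, feature_matrix_factory):
        fm, _, _ = feature_matrix_factory(seed=2)
        a = lt.fit_subtypes(fm, k_range=(2, 3, 4), gap_B=5, seed=3)
        b = lt.fit_subtypes(fm, k_range=(2, 3, 4), gap_B=5, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.k == b.k

    def test_recovers_planted_k_and_labels(self, feature_matrix_factory):
        fm, truth, _ = feature_matrix_factory(seed=8)
        model = lt.fit_subtypes(fm, k_range=(2, 3, 4, 5), gap_B=10, seed=8)
        assert model.k == 3
        assert adjusted_rand_score(truth, model.labels) >= 0.9

    def test_no_structure_yields_flat_low_cpi(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.normal(size=(60, 40)), index=[f"s{i}" for i in range(60)]
        )
        curve = lt.cpi(FeatureMatrix(continuous=df), (2, 3, 4), seed=0)
        assert curve.max() < 0.5

    def test_silhouette_on_consensus_peaks_at_true_k(self, feature_matrix_factory):
        fm, truth, _ = feature_matrix_factory(seed=5)
        means = {}
        for k in range(2, 7):
            ens = lt.run_base_partitions(fm, k, seed=5)
            cm = lt.consensus_matrix(ens)
            labels = lt.consensus_labels(cm, k)
            _, _, means[k] = lt.silhouette_scores(labels, cm.distance())
        assert max(means, key=means.get) == 3
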