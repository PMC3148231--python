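"""Profiles, average-linkage clustering vs a brute-force oracle, PCA, Pearson."""

import io

import numpy as np
import pandas as pd
import pytest

from mirsig.io_formats import ConfigurationError
from mirsig.report import (
    fold_change_profile_matrix,
    hierarchical_cluster,
    pairwise_euclidean,
    pca,
    pearson_r,
)
from tests.test_signature import record


def upgma_oracle(X: np.ndarray, labels):
    """Naive average-linkage agglomeration; lowest-index pair on ties."""
    n = len(X)
    full = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    clusters = {i: frozenset([labels[i]]) for i in range(n)}
    leaf_idx = {i: [i] for i in range(n)}
    active = sorted(clusters)
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai, a in enumerate(active):
            for b in active[ai + 1:]:
                d = np.mean([full[i, j] for i in leaf_idx[a] for j in leaf_idx[b]])
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        clusters[next_id] = clusters[a] | clusters[b]
        leaf_idx[next_id] = leaf_idx[a] + leaf_idx[b]
        merges.append((clusters[next_id], d))
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return merges


class TestProfileMatrix:
    def test_log2_ratios(self):
        profiles = fold_change_profile_matrix(
            {
                "p1": [record("m1", fc=8.0)],
                "p2": [record("m1", fc=-8.0)],
            }
        )
        assert profiles.loc["p1", "m1"] == pytest.approx(3.0)
        assert profiles.loc["p2", "m1"] == pytest.approx(-3.0)

    def test_missing_features_are_nan(self):
        profiles = fold_change_profile_matrix(
            {"p1": [record("m1"), record("m2")], "p2": [record("m1")]}
        )
        assert np.isnan(profiles.loc["p2", "m2"])

    def test_single_profile_rejected(self):
        with pytest.raises(ConfigurationError):
            fold_change_profile_matrix({"p1": [record("m1")]})


class TestHierarchicalCluster:
    def test_three_points_on_a_line_merge_nearest_first(self):
        profiles = pd.DataFrame([[0.0], [1.0], [10.0]], index=["a", "b", "c"])
        tree = hierarchical_cluster(profiles)
        merges = tree.merge_order()
        assert merges[0][0] == frozenset({"a", "b"})
        assert merges[0][1] == pytest.approx(1.0)

    def test_duplicate_profiles_merge_at_height_zero(self):
        profiles = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=["a", "b", "c"])
        tree = hierarchical_cluster(profiles)
        assert tree.merge_order()[0] == (frozenset({"a", "b"}), 0.0)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(0)
        profiles = pd.DataFrame(rng.normal(size=(10, 4)))
        tree = hierarchical_cluster(profiles)
        h = tree.heights
        assert (np.diff(h) >= -1e-12).all()

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for trial in range(20):
            n = int(rng.integers(3, 9))
            X = rng.normal(size=(n, 3))
            labels = [f"p{i}" for i in range(n)]
            profiles = pd.DataFrame(X, index=labels)
            got = hierarchical_cluster(profiles).merge_order()
            expected = upgma_oracle(X, labels)
            assert [m for m, _ in got] == [m for m, _ in expected]
            np.testing.assert_allclose(
                [h for _, h in got], [h for _, h in expected], rtol=1e-9
            )

    def test_newick_round_trips_through_biopython(self):
        from Bio import Phylo

        rng = np.random.default_rng(2)
        profiles = pd.DataFrame(rng.normal(size=(6, 3)), index=[f"s{i}" for i in range(6)])
        newick = hierarchical_cluster(profiles).to_newick()
        tree = Phylo.read(io.StringIO(newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == [f"s{i}" for i in range(6)]

    def test_pairwise_complete_distance_rescales_missing(self):
        profiles = pd.DataFrame(
            [[0.0, 0.0], [3.0, np.nan]], index=["a", "b"], columns=["f1", "f2"]
        )
        # one shared feature of two -> squared distance scaled by 2/1
        assert pairwise_euclidean(profiles)[0] == pytest.approx(np.sqrt(9 * 2))

    def test_no_shared_features_is_error(self):
        profiles = pd.DataFrame(
            [[1.0, np.nan], [np.nan, 1.0]], index=["a", "b"]
        )
        with pytest.raises(ConfigurationError):
            pairwise_euclidean(profiles)


class TestPca:
    def test_pc1_aligned_with_dominant_direction(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=200)
        X = np.outer(t, [1.0, 1.0]) + rng.normal(scale=0.01, size=(200, 2))
        result = pca(pd.DataFrame(X), n_components=2)
        np.testing.assert_allclose(
            result.loadings["PC1"].to_numpy(), [1 / np.sqrt(2)] * 2, atol=0.01
        )

    def test_variance_fractions_sum_to_one_with_all_components(self):
        rng = np.random.default_rng(1)
        result = pca(pd.DataFrame(rng.normal(size=(10, 4))))
        assert result.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        assert (result.explained_variance_ratio >= 0).all()

    def test_full_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 5))
        df = pd.DataFrame(X)
        result = pca(df)
        recon = result.scores.to_numpy() @ result.loadings.to_numpy().T + X.mean(axis=0)
        assert np.abs(recon - X).max() / np.abs(X).max() < 1e-8

    def test_excess_components_truncated_with_warning(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="rank"):
            result = pca(pd.DataFrame(rng.normal(size=(3, 5))), n_components=4)
        assert result.scores.shape[1] == 2

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 4))
        r1 = pca(pd.DataFrame(X))
        r2 = pca(pd.DataFrame(X.copy()))
        pd.testing.assert_frame_equal(r1.scores, r2.scores)
        for c in r1.loadings:
            col = r1.loadings[c]
            assert col.iloc[int(np.argmax(np.abs(col)))] > 0


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_pairwise_complete_over_missing(self):
        x = np.array([1.0, 2.0, 3.0, np.nan, 4.0])
        y = np.array([2.0, 4.0, 6.0, 100.0, 8.0])
        assert pearson_r(x, y) == pytest.approx(1.0)

    def test_sampling_distribution_around_known_rho(self):
        rho, n = 0.78, 120
        cov = [[1.0, rho], [rho, 1.0]]
        estimates = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            estimates.append(pearson_r(xy[:, 0], xy[:, 1]))
        assert abs(np.mean(estimates) - rho) < 0.05
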