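"""Distances, Ward.D2 clustering, PCA, PLS-DA, Mann-Whitney."""

import numpy as np
import pandas as pd
import pytest

import kmersig as ks
from kmersig.alphabet import kmer_strings


def frame(rows, index=None):
    return pd.DataFrame(
        np.asarray(rows, dtype=float),
        index=index or [f"g{i}" for i in range(len(rows))],
    )


class TestDistances:
    def test_3_4_5(self):
        D = ks.euclidean_distance_matrix(frame([[0, 0], [3, 4]]))
        assert D.values[0, 1] == pytest.approx(5.0)

    def test_identical_rows_zero(self):
        D = ks.euclidean_distance_matrix(frame([[1, 2], [1, 2]]))
        assert D.values[0, 1] == 0.0

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 8))
        perm = rng.permutation(8)
        D1 = ks.euclidean_distance_matrix(frame(X))
        D2 = ks.euclidean_distance_matrix(frame(X[:, perm]))
        np.testing.assert_allclose(D1.values, D2.values)

    def test_nan_rejected_naming_row(self):
        X = frame([[0, 1], [np.nan, 2], [3, 4]])
        with pytest.raises(ValueError, match="g1"):
            ks.euclidean_distance_matrix(X)


class TestWard:
    def test_nearest_pair_merges_first(self):
        D = ks.euclidean_distance_matrix(frame([[0.0], [0.1], [10.0]]))
        dend = ks.ward_cluster(D)
        assert set(dend.linkage[0, :2]) == {0, 1}

    def test_coincident_points_merge_at_zero(self):
        D = ks.euclidean_distance_matrix(frame([[1.0], [1.0], [5.0]]))
        dend = ks.ward_cluster(D)
        assert dend.linkage[0, 2] == 0.0

    def test_two_tight_pairs_top_split(self):
        X = frame([[0.0], [0.1], [10.0], [10.1]], index=list("abcd"))
        dend = ks.ward_cluster(ks.euclidean_distance_matrix(X))
        labels = dend.cut(2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_heights_monotone(self, demo_profiles):
        dend = ks.ward_cluster(ks.euclidean_distance_matrix(demo_profiles))
        h = dend.heights()
        assert np.all(np.diff(h) >= -1e-12)

    def test_newick_round_trip_topology(self):
        pytest.importorskip("skbio")
        from io import StringIO

        from skbio import TreeNode

        rng = np.random.default_rng(3)
        X = frame(rng.normal(size=(7, 4)), index=[f"leaf{i}" for i in range(7)])
        dend = ks.ward_cluster(ks.euclidean_distance_matrix(X))
        tree = TreeNode.read(StringIO(dend.to_newick()))
        assert {t.name for t in tree.tips()} == set(X.index)
        # sibling structure of the first merge survives serialization
        first = {X.index[int(i)] for i in dend.linkage[0, :2]}
        tip = tree.find(sorted(first)[0])
        siblings = {t.name for t in tip.parent.tips()}
        assert first <= siblings


class TestPCA:
    def test_collinear_points_single_component(self):
        t = np.arange(5, dtype=float)
        res = ks.pca(frame(np.column_stack([t, 2 * t])))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, demo_profiles):
        res = ks.pca(demo_profiles)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_scores_preserve_standardized_distances(self):
        rng = np.random.default_rng(5)
        X = frame(rng.normal(size=(6, 4)))
        res = ks.pca(X)
        Z = X.to_numpy()
        Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(res.scores.to_numpy()), pdist(Z), atol=1e-9)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ks.pca(frame(np.ones((4, 3))))

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(6)
        X = frame(rng.normal(size=(8, 5)))
        r1, r2 = ks.pca(X), ks.pca(X)
        np.testing.assert_array_equal(r1.loadings.to_numpy(), r2.loadings.to_numpy())
        for a in range(r1.loadings.shape[1]):
            col = r1.loadings.iloc[:, a]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0


class TestPLSDA:
    def test_separable_case_perfect_accuracy_and_vip(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 0.01, size=(60, 10))
        X[:30, 3] += 5.0  # one feature carries the whole separation
        M = pd.DataFrame(X, index=[f"g{i}" for i in range(60)],
                         columns=[f"f{j:02d}" for j in range(10)])
        labels = ["A"] * 30 + ["B"] * 30
        res = ks.plsda(M, labels, n_grid=range(1, 4), seed=0)
        assert res.accuracy["mean_accuracy"].max() == pytest.approx(1.0)
        assert res.vip.idxmax() == "f03"
        assert float((res.vip**2).mean()) == pytest.approx(1.0, abs=1e-6)

    def test_null_labels_near_chance(self):
        rng = np.random.default_rng(8)
        accs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(20, 10)),
                             index=[f"g{i}" for i in range(20)])
            labels = list("AB") * 10
            res = ks.plsda(X, labels, n_grid=[1, 2], folds=5, repeats=2, seed=seed)
            accs.append(res.accuracy["mean_accuracy"].max())
        # selection maximizes over the grid, so the null accuracy sits a
        # little above 0.5 but nowhere near separation
        assert 0.35 < np.mean(accs) < 0.7

    def test_single_class_rejected(self):
        X = frame(np.random.default_rng(0).normal(size=(10, 4)))
        with pytest.raises(ValueError):
            ks.plsda(X, ["A"] * 10, seed=0)

    def test_planted_discriminant_recovery(self):
        recalls = []
        for seed in range(5):
            M, labels, planted = _halophile_scenario(seed)
            res = ks.plsda(M, labels, n_grid=range(1, 4), seed=seed)
            top = ks.top_discriminant(res, 10)
            recalls.append(len(set(planted) & set(top.feature)) / 10)
        assert np.mean(recalls) >= 0.8

    def test_top_discriminant_direction_and_clamp(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 6))
        X[:10, 0] += 3.0
        M = pd.DataFrame(X, index=[f"g{i}" for i in range(20)],
                         columns=[f"f{j}" for j in range(6)])
        res = ks.plsda(M, ["A"] * 10 + ["B"] * 10, n_grid=[1, 2], seed=0)
        top = ks.top_discriminant(res, 3)
        assert top.loc[top.feature == "f0", "high_in"].item() == "A"
        assert len(ks.top_discriminant(res, 0)) == 0
        assert len(ks.top_discriminant(res, 99)) == 6


def _halophile_scenario(seed):
    """Two niche classes; ten 5-mers enriched in the 'halophile' class."""
    rng = np.random.default_rng(seed)
    p = 1024
    planted_idx = rng.choice(p, 10, replace=False)
    X = np.full((40, p), 1 / p) + rng.normal(0, 2e-4, size=(40, p))
    X[:20, planted_idx] += 1.5e-3
    X = np.abs(X)
    X /= X.sum(1, keepdims=True)
    M = pd.DataFrame(X, index=[f"g{i}" for i in range(40)], columns=kmer_strings(5))
    labels = ["halophile"] * 20 + ["non-halophile"] * 20
    return M, labels, [M.columns[i] for i in planted_idx]


class TestMannWhitney:
    def test_identical_multisets_p_one(self):
        assert ks.mann_whitney([1, 2, 2, 3], [1, 2, 2, 3]) == 1.0

    def test_complete_separation_exact(self):
        assert ks.mann_whitney([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_monotone_transform_invariance(self):
        a = [0.1, 0.5, 2.0, 3.5, 8.0]
        b = [0.3, 1.2, 2.4, 9.0, 11.0]
        p1 = ks.mann_whitney(a, b)
        p2 = ks.mann_whitney(np.log(a), np.log(b))
        assert p1 == pytest.approx(p2)

    def test_large_sample_asymptotic_path(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 50)
        p = ks.mann_whitney(a, b)
        assert 0 < p < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ks.mann_whitney([], [1, 2])
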