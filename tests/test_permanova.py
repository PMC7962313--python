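"""PERMANOVA: Gower centering, sequential decomposition, commonality."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import kmersig as ks
from kmersig.multivariate import DistanceMatrix


def dist_1d(values):
    X = pd.DataFrame({"x": list(map(float, values))},
                     index=[f"g{i}" for i in range(len(values))])
    return ks.euclidean_distance_matrix(X)


def meta_for(D, **columns):
    return pd.DataFrame({"id": D.ids, **columns})


class TestGowerCenter:
    def test_two_points_trace(self):
        D = dist_1d([0, 3])
        G = ks.gower_center(D)
        assert np.trace(G) == pytest.approx(9 / 2)

    def test_identical_points_zero(self):
        G = ks.gower_center(dist_1d([2, 2, 2]))
        np.testing.assert_allclose(G, 0.0, atol=1e-12)

    def test_row_sums_zero(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(6, 3)), index=[f"g{i}" for i in range(6)])
        G = ks.gower_center(ks.euclidean_distance_matrix(X))
        np.testing.assert_allclose(G.sum(axis=1), 0.0, atol=1e-9)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestSequential:
    def test_pure_between_group_structure(self):
        D = dist_1d([0, 0, 1, 1])
        res = ks.permanova_sequential(D, meta_for(D, g=list("AABB")), ["g"], n_perm=0)
        assert res.r2("g") == pytest.approx(1.0, abs=1e-9)
        assert res.table.loc["Residual", "SS"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_half_r2(self):
        # SS_total = 2, SS_within = 1 for points {0,1,1,2} split in pairs
        D = dist_1d([0, 1, 1, 2])
        res = ks.permanova_sequential(D, meta_for(D, g=list("AABB")), ["g"], n_perm=0)
        assert res.r2("g") == pytest.approx(0.5, abs=1e-9)

    def test_matches_classical_anova_on_1d(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=18)
        groups = ["A"] * 6 + ["B"] * 6 + ["C"] * 6
        D = dist_1d(x)
        res = ks.permanova_sequential(D, meta_for(D, g=groups), ["g"], n_perm=0)
        f_ref = scipy.stats.f_oneway(x[:6], x[6:12], x[12:]).statistic
        grand = x.mean()
        ss_total = ((x - grand) ** 2).sum()
        ss_between = sum(6 * (x[i : i + 6].mean() - grand) ** 2 for i in (0, 6, 12))
        assert res.table.loc["g", "F"] == pytest.approx(f_ref, abs=1e-9)
        assert res.r2("g") == pytest.approx(ss_between / ss_total, abs=1e-9)

    def test_quantitative_covariate_single_df(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        D = dist_1d(x)
        meta = meta_for(D, gc=rng.uniform(0.3, 0.7, 12))
        res = ks.permanova_sequential(D, meta, ["gc"], n_perm=0)
        assert res.table.loc["gc", "df"] == 1

    def test_seed_determinism_and_p_floor(self):
        D = dist_1d([0, 0, 0.2, 1, 1, 1.2])
        meta = meta_for(D, g=list("AAABBB"))
        r1 = ks.permanova_sequential(D, meta, ["g"], n_perm=99, seed=5)
        r2 = ks.permanova_sequential(D, meta, ["g"], n_perm=99, seed=5)
        assert r1.p_value("g") == r2.p_value("g")
        assert r1.p_value("g") >= 1 / 100

    def test_term_order_changes_split_not_total(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=16)
        a = list("AB") * 8
        b = ["X"] * 6 + ["Y"] * 10
        D = dist_1d(x)
        r_ab = ks.permanova_sequential(D, meta_for(D, a=a, b=b), ["a", "b"], n_perm=0)
        r_ba = ks.permanova_sequential(D, meta_for(D, a=a, b=b), ["b", "a"], n_perm=0)
        total_ab = r_ab.table["SS"].drop("Total").sum()
        total_ba = r_ba.table["SS"].drop("Total").sum()
        assert total_ab == pytest.approx(total_ba, abs=1e-9)

    def test_formula_parsing(self):
        D = dist_1d([0, 0, 1, 1])
        res = ks.permanova_formula(D, meta_for(D, g=list("AABB")), "D ~ g", n_perm=0)
        assert res.model == "D ~ g"
        with pytest.raises(ValueError):
            ks.permanova_formula(D, meta_for(D, g=list("AABB")), "no tilde", n_perm=0)

    def test_unknown_column_rejected(self):
        D = dist_1d([0, 1, 2])
        with pytest.raises(ValueError, match="unknown"):
            ks.permanova_sequential(D, meta_for(D, g=list("ABB")), ["nope"], n_perm=0)

    def test_confounded_term_dropped(self, caplog):
        D = dist_1d([0, 0, 1, 1])
        meta = meta_for(D, a=list("AABB"), b=list("AABB"))
        with caplog.at_level("WARNING"):
            res = ks.permanova_sequential(D, meta, ["a", "b"], n_perm=0)
        assert "b" not in res.table.index
        assert "no degrees of freedom" in caplog.text


class TestCommonality:
    def test_duplicated_factor_fully_shared(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 1, 6), rng.normal(3, 1, 6)])
        g = list("AAAAAABBBBBB")
        D = dist_1d(x)
        meta = meta_for(D, a=g, b=g)
        part = ks.commonality(D, meta, "a", "b")
        r2 = ks.permanova_sequential(D, meta, ["a"], n_perm=0).r2("a")
        assert part.shared == pytest.approx(r2, abs=1e-9)
        assert part.unique_a == pytest.approx(0.0, abs=1e-9)
        assert part.unique_b == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_design_no_shared(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(16, 4)), index=[f"g{i}" for i in range(16)])
        D = ks.euclidean_distance_matrix(X)
        meta = meta_for(D, a=list("AABB") * 4, b=list("XY") * 8)
        part = ks.commonality(D, meta, "a", "b")
        assert part.shared == pytest.approx(0.0, abs=1e-9)

    def test_nested_niche_fully_shared_with_order(self, demo_profiles, demo_metadata):
        cells = demo_metadata[demo_metadata.type == "cell"].index
        D = ks.euclidean_distance_matrix(demo_profiles.loc[cells])
        meta = demo_metadata.loc[cells].reset_index()
        part = ks.commonality(D, meta, "niche", "order")
        r2_niche = ks.permanova_sequential(D, meta, ["niche"], n_perm=0).r2("niche")
        # niche is determined by order here, so its variance is entirely
        # shared with the taxonomic signal
        assert part.shared == pytest.approx(r2_niche, abs=1e-9)
        assert part.unique_a == pytest.approx(0.0, abs=1e-9)
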