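"""NIPALS PCA/PLS-DA against independent oracles; correlation loadings."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import nmrmodal as nm
from nmrmodal.chemometrics import (
    CorrelationLoadingMap,
    export_loading_map,
    export_model,
)
from nmrmodal.errors import (
    ClassCountError,
    DegenerateScoresError,
    InvalidParameterError,
    RankError,
)

from _oracles import align_signs, pca_eig, pls1_nipals_textbook


def _fm(X, labels=None, grid=None):
    n, p = X.shape
    grid = grid or (1, p)
    return nm.FeatureMatrix(X, [f"s{i}" for i in range(n)], grid,
                            group_labels=labels)


class TestPCA:
    def test_rank_one_data_explained_fully_by_pc1(self):
        v = np.array([1.0, -2.0, 0.5, 3.0])
        X = np.outer([1.0, 2.0, 3.0, 4.0], v)
        res = nm.pca_fit(_fm(X), n_components=1)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_eigendecomposition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((6, 10))
        k = 4
        res = nm.pca_fit(_fm(X, grid=(2, 5)), n_components=k)
        T_ref, V_ref, ev_ref = pca_eig(X, k)
        np.testing.assert_allclose(res.loadings, V_ref, atol=1e-6)
        np.testing.assert_allclose(res.scores, T_ref, atol=1e-6)
        np.testing.assert_allclose(res.explained_variance_fraction, ev_ref, atol=1e-6)

    def test_matches_sklearn_cross_check(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        X = np.random.default_rng(8).standard_normal((8, 15))
        res = nm.pca_fit(_fm(X, grid=(3, 5)), n_components=3)
        ref = sklearn_pca(n_components=3).fit(X)
        np.testing.assert_allclose(
            np.abs(res.loadings.T), np.abs(ref.components_), atol=1e-6
        )
        np.testing.assert_allclose(
            res.explained_variance_fraction, ref.explained_variance_ratio_, atol=1e-6
        )

    def test_structural_invariants(self):
        X = np.random.default_rng(4).standard_normal((7, 12))
        k = 5
        res = nm.pca_fit(_fm(X, grid=(3, 4)), n_components=k)
        # unit-norm loadings
        np.testing.assert_allclose(
            np.linalg.norm(res.loadings, axis=0), 1.0, atol=1e-8
        )
        # mutually orthogonal scores
        G = res.scores.T @ res.scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) <= 1e-6 * np.max(np.diag(G))
        # non-increasing fractions in [0, 1]
        ev = res.explained_variance_fraction
        assert np.all(ev >= -1e-12) and np.all(ev <= 1 + 1e-12)
        assert np.all(np.diff(ev) <= 1e-10)

    def test_full_rank_fractions_sum_to_one(self):
        X = np.random.default_rng(5).standard_normal((6, 9))
        res = nm.pca_fit(_fm(X, grid=(3, 3)), n_components=5)  # min(n-1, p)
        assert res.explained_variance_fraction.sum() == pytest.approx(1.0, abs=1e-6)

    def test_deflation_leaves_residual_orthogonal_to_scores(self):
        X = np.random.default_rng(6).standard_normal((6, 8))
        res = nm.pca_fit(_fm(X, grid=(2, 4)), n_components=3)
        Xc = X - res.column_means
        residual = Xc - res.scores @ res.loadings.T
        cross = res.scores.T @ residual
        assert np.max(np.abs(cross)) <= 1e-6 * np.linalg.norm(Xc)

    def test_group_separation_on_synthetic_cohort(self, demo_pca, demo_matrices):
        # PC1 separates the two latent states by score sign (oracle: the
        # centroid-difference projection assigns the same side to every sample)
        _, fm = demo_matrices
        labels = np.array(fm.group_labels)
        pc1 = demo_pca.scores[:, 0]
        signs = {g: set(np.sign(pc1[labels == g])) for g in set(labels)}
        assert all(len(s) == 1 for s in signs.values())
        assert signs["precursor"] != signs["progressed"]
        Xc = fm.values - fm.values.mean(axis=0)
        centroid_axis = (Xc[labels == "progressed"].mean(axis=0)
                         - Xc[labels == "precursor"].mean(axis=0))
        proj_sign = np.sign(Xc @ centroid_axis)
        assert np.all(proj_sign == np.sign(pc1)) or np.all(proj_sign == -np.sign(pc1))

    def test_too_many_components_rejected(self):
        X = np.random.default_rng(0).standard_normal((4, 6))
        with pytest.raises(RankError):
            nm.pca_fit(_fm(X, grid=(2, 3)), n_components=4)


class TestPLSDA:
    def test_single_informative_column_separates(self):
        rng = np.random.default_rng(0)
        y = np.array([1.0, 1, 1, 1, -1, -1, -1, -1])
        X = np.zeros((8, 6))
        X[:, 2] = y
        labels = ["A" if v > 0 else "B" for v in y]
        res = nm.plsda_fit(_fm(X, labels, grid=(2, 3)), n_factors=1)
        t1 = res.x_scores[:, 0]
        coded = np.array([res.class_coding[l] for l in labels])
        assert np.all(np.sign(t1) == np.sign(coded))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_textbook_nipals_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        X = rng.standard_normal((8, 12))
        labels = ["A"] * 4 + ["B"] * 4
        y = np.array([-1.0] * 4 + [1.0] * 4)
        res = nm.plsda_fit(_fm(X, labels, grid=(3, 4)), n_factors=3)
        T_ref, P_ref, W_ref, q_ref = pls1_nipals_textbook(X, y, 3)
        np.testing.assert_allclose(res.x_scores, align_signs(res.x_scores, T_ref),
                                   atol=1e-6)
        np.testing.assert_allclose(res.x_weights, align_signs(res.x_weights, W_ref),
                                   atol=1e-6)
        np.testing.assert_allclose(np.abs(res.y_loadings), np.abs(q_ref), atol=1e-6)

    def test_matches_sklearn_first_factor(self):
        PLSRegression = pytest.importorskip("sklearn.cross_decomposition").PLSRegression
        rng = np.random.default_rng(9)
        X = rng.standard_normal((10, 7))
        labels = ["A"] * 5 + ["B"] * 5
        res = nm.plsda_fit(_fm(X, labels, grid=(1, 7)), n_factors=2)
        ref = PLSRegression(n_components=2, scale=False).fit(
            X, np.array([-1.0] * 5 + [1.0] * 5)
        )
        np.testing.assert_allclose(
            np.abs(res.x_scores[:, 0]), np.abs(ref.x_scores_[:, 0]), atol=1e-6
        )

    def test_relabeling_negates_factor1_scores(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((6, 9))
        labels = ["A", "A", "A", "B", "B", "B"]
        swapped = ["B", "B", "B", "A", "A", "A"]
        a = nm.plsda_fit(_fm(X, labels, grid=(3, 3)), n_factors=1)
        b = nm.plsda_fit(_fm(X, swapped, grid=(3, 3)), n_factors=1)
        np.testing.assert_allclose(b.x_scores[:, 0], -a.x_scores[:, 0], atol=1e-9)

    def test_factor1_sign_convention(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((6, 5))
        labels = ["A", "A", "A", "B", "B", "B"]
        res = nm.plsda_fit(_fm(X, labels, grid=(1, 5)), n_factors=1)
        pos_class = [k for k, v in res.class_coding.items() if v == 1.0][0]
        t1 = res.x_scores[:, 0]
        pos_mean = t1[[l == pos_class for l in labels]].mean()
        neg_mean = t1[[l != pos_class for l in labels]].mean()
        assert pos_mean > neg_mean

    def test_score_orthogonality(self):
        X = np.random.default_rng(4).standard_normal((9, 11))
        labels = ["A"] * 5 + ["B"] * 4
        res = nm.plsda_fit(_fm(X, labels, grid=(1, 11)), n_factors=4)
        G = res.x_scores.T @ res.x_scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) <= 1e-6 * np.max(np.diag(G))

    @pytest.mark.parametrize("labels", [["A"] * 6, ["A", "A", "B", "B", "C", "C"]])
    def test_wrong_class_count_rejected(self, labels):
        X = np.random.default_rng(0).standard_normal((6, 4))
        with pytest.raises(ClassCountError):
            nm.plsda_fit(_fm(X, labels, grid=(2, 2)), n_factors=1)

    def test_single_sample_class_warns(self):
        X = np.random.default_rng(0).standard_normal((4, 4))
        with pytest.warns(UserWarning, match="single sample"):
            nm.plsda_fit(_fm(X, ["A", "B", "B", "B"], grid=(2, 2)), n_factors=1)

    def test_perfect_training_separation_on_cohort(self, demo_matrices):
        # between-group effect far above jitter: Factor-1 sign-classifies
        # every training sample
        _, fm = demo_matrices
        res = nm.plsda_fit(fm, n_factors=2)
        assert res.factor1_labels() == fm.group_labels


class TestCorrelationLoadings:
    def test_self_and_anti_correlation(self):
        rng = np.random.default_rng(5)
        s = rng.standard_normal(8)
        X = rng.standard_normal((8, 4))
        X[:, 1] = s
        X[:, 2] = -s
        cmap = nm.correlation_loadings(_fm(X, grid=(2, 2)), s)
        r = cmap.r_values.ravel()
        assert r[1] == pytest.approx(1.0, abs=1e-12)
        assert r[2] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_column_undefined_and_unmasked(self):
        rng = np.random.default_rng(6)
        s = rng.standard_normal(6)
        X = rng.standard_normal((6, 3))
        X[:, 0] = 7.0  # constant
        cmap = nm.correlation_loadings(_fm(X, grid=(1, 3)), s)
        assert np.isnan(cmap.r_values[0, 0])
        assert not cmap.mask[0, 0]

    def test_constant_scores_rejected(self):
        X = np.random.default_rng(7).standard_normal((5, 4))
        with pytest.raises(DegenerateScoresError):
            nm.correlation_loadings(_fm(X, grid=(2, 2)), np.ones(5))

    def test_back_projection_uses_row_major_grid(self):
        rng = np.random.default_rng(8)
        s = rng.standard_normal(6)
        X = rng.standard_normal((6, 6))
        X[:, 5] = s  # grid (2,3): index 5 -> cell (1, 2)
        cmap = nm.correlation_loadings(_fm(X, grid=(2, 3)), s)
        assert cmap.r_values[1, 2] == pytest.approx(1.0, abs=1e-12)


class TestThresholdMask:
    def test_boundary_inclusive_at_0_4(self):
        cmap = CorrelationLoadingMap(np.array([[0.39, 0.40, -0.41]]))
        np.testing.assert_array_equal(
            nm.threshold_mask(cmap, 0.4), [[False, True, True]]
        )

    def test_threshold_one_keeps_only_exact_unit(self):
        cmap = CorrelationLoadingMap(np.array([[1.0, -1.0, 0.999999]]))
        np.testing.assert_array_equal(
            nm.threshold_mask(cmap, 1.0), [[True, True, False]]
        )

    def test_all_undefined_gives_all_false(self):
        cmap = CorrelationLoadingMap(np.full((2, 2), np.nan))
        assert not nm.threshold_mask(cmap, 0.4).any()

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_invalid_threshold_rejected(self, bad):
        cmap = CorrelationLoadingMap(np.zeros((1, 1)))
        with pytest.raises(InvalidParameterError):
            nm.threshold_mask(cmap, bad)


class TestExports:
    def test_score_tables_round_trip_and_axis_names(self, tmp_path, demo_pca,
                                                    demo_matrices):
        _, fm = demo_matrices
        export_model(
            demo_pca,
            score_plot_path=tmp_path / "scores.png",
            tables_dir=tmp_path,
            component_pair=(1, 5),
            group_labels=fm.group_labels,
        )
        df = pd.read_csv(tmp_path / "scores.tsv", sep="\t")
        assert list(df.columns[:2]) == ["sample_id", "group_label"]
        assert "PC-1" in df.columns and "PC-5" in df.columns
        np.testing.assert_allclose(
            df[[f"PC-{i}" for i in range(1, 6)]].to_numpy(),
            demo_pca.scores,
            rtol=1e-11,
        )
        ev = pd.read_csv(tmp_path / "explained_variance.tsv", sep="\t")
        np.testing.assert_allclose(
            ev["explained_variance_fraction"],
            demo_pca.explained_variance_fraction,
            rtol=1e-11,
        )
        assert (tmp_path / "scores.png").exists()

    def test_component_pair_out_of_range(self, demo_pca):
        with pytest.raises(IndexError):
            export_model(demo_pca, component_pair=(1, 6))

    def test_loading_map_export_dimensions(self, tmp_path):
        rng = np.random.default_rng(11)
        cmap = CorrelationLoadingMap(rng.uniform(-1, 1, size=(4, 8)))
        export_loading_map(cmap, plot_path=tmp_path / "map.png",
                           ascii_path=tmp_path / "map.txt")
        back = np.loadtxt(tmp_path / "map.txt")
        assert back.shape == (4, 8)
        np.testing.assert_allclose(back, cmap.r_values, atol=1e-8)
        assert (tmp_path / "map.png").exists()
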