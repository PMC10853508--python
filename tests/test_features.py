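"""PCA decomposition, reconstruction identity, t-score ranking, contrast
maps and SVM weight-map rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirscv import (
    BetaPCA,
    LinearSVM,
    TScoreSelector,
    fit_pca,
    group_contrast,
    loo_svm,
    rank_pcs,
    simulate_feature_table,
    svm_weight_map,
)


def random_matrix(seed, n=12, p=20):
    return np.random.default_rng(seed).standard_normal((n, p))


class TestBetaPCA:
    def test_rank_one_matrix_fully_explained(self):
        u = np.arange(1.0, 9.0)
        v = np.linspace(-1, 1, 15)
        pca = fit_pca(np.outer(u, v), n_pc=1)
        assert pca.explained_fraction_[0] == pytest.approx(1.0, abs=1e-10)

    def test_reference_shapes_and_orthonormality(self):
        """A 36 x 54 beta matrix decomposed into 32 components gives
        36 x 32 scores and orthonormal component rows."""
        X = random_matrix(0, 36, 54)
        pca = fit_pca(X, n_pc=32)
        assert pca.scores_.shape == (36, 32)
        gram = pca.components_ @ pca.components_.T
        np.testing.assert_allclose(gram, np.eye(32), atol=1e-8)

    def test_scores_equal_centered_projection(self):
        X = random_matrix(1)
        pca = fit_pca(X, n_pc=8)
        manual = (X - X.mean(axis=0)) @ pca.components_.T
        np.testing.assert_allclose(pca.scores_, manual, atol=1e-8)

    def test_explained_fraction_monotone_and_bounded(self):
        pca = fit_pca(random_matrix(2), n_pc=10)
        ef = pca.explained_fraction_
        assert (np.diff(ef) <= 1e-12).all()
        assert ((ef >= 0) & (ef <= 1)).all()
        assert ef.sum() <= 1 + 1e-10

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(random_matrix(0, 5, 10), n_pc=5)  # > n-1
        with pytest.raises(ValueError):
            fit_pca(np.ones((6, 4)), n_pc=2)  # zero variance

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_full_rank_reconstruction_identity(self, seed):
        """Every subject's map is exactly the mean plus the score-weighted
        component sum at full rank (random matrices)."""
        rng = np.random.default_rng(seed)
        n, p = int(rng.integers(4, 12)), int(rng.integers(3, 15))
        X = rng.standard_normal((n, p))
        pca = fit_pca(X, n_pc=min(n - 1, p))
        for i in range(n):
            np.testing.assert_allclose(pca.reconstruct(i), X[i], atol=1e-8)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_explained_variance_sums_to_one_at_full_rank(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((10, 6))
        pca = fit_pca(X, n_pc=6)
        assert pca.explained_fraction_.sum() == pytest.approx(1.0, abs=1e-8)

    def test_reconstruct_k_zero_gives_mean(self):
        X = random_matrix(3)
        pca = fit_pca(X, n_pc=5)
        np.testing.assert_allclose(pca.reconstruct(0, 0), X.mean(axis=0), atol=1e-12)

    def test_rank_one_data_reconstructed_with_one_component(self):
        u = np.array([1.0, 2.0, -1.0, 0.5, 3.0])
        v = np.linspace(0, 1, 9)
        X = np.outer(u, v)
        pca = fit_pca(X, n_pc=1)
        for i in range(5):
            np.testing.assert_allclose(pca.reconstruct(i, 1), X[i], atol=1e-8)

    def test_reconstruct_index_out_of_range(self):
        pca = fit_pca(random_matrix(4), n_pc=3)
        with pytest.raises(IndexError):
            pca.reconstruct(99)


class TestRankPCs:
    def test_shifted_component_ranks_first(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal((30, 8))
        labels = np.array(["TD"] * 15 + ["ASD"] * 15)
        scores[labels == "ASD", 3] += 5.0
        ranking = rank_pcs(scores, labels)
        assert ranking.order[0] == 3
        # cross-check the top t against scipy
        from scipy.stats import ttest_ind

        t_ref = ttest_ind(
            scores[labels == "TD", 3], scores[labels == "ASD", 3], equal_var=True
        ).statistic
        assert ranking.t_values[3] == pytest.approx(t_ref, rel=1e-10)

    def test_rank_uniform_under_random_labels(self):
        """With labels independent of scores, each PC is equally likely to
        rank first (chi-square goodness of fit)."""
        from scipy.stats import chisquare

        rng = np.random.default_rng(1)
        p = 8
        firsts = np.zeros(p)
        labels = np.array(["TD"] * 10 + ["ASD"] * 10)
        for _ in range(1000):
            scores = rng.standard_normal((20, p))
            firsts[rank_pcs(scores, rng.permutation(labels)).order[0]] += 1
        assert chisquare(firsts).pvalue > 0.001

    def test_subset_exclusion_changes_statistic(self):
        rng = np.random.default_rng(2)
        scores = rng.standard_normal((20, 5))
        labels = np.array(["TD"] * 10 + ["ASD"] * 10)
        full = rank_pcs(scores, labels)
        nested = rank_pcs(scores, labels, subject_subset=np.arange(19))
        assert not np.allclose(full.t_values, nested.t_values)
        np.testing.assert_array_equal(nested.fitted_on, np.arange(19))

    def test_relabeling_and_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.standard_normal((20, 6))
        labels = np.array(["TD"] * 10 + ["ASD"] * 10)
        swapped = np.where(labels == "TD", "ASD", "TD")
        r1, r2 = rank_pcs(scores, labels), rank_pcs(scores, swapped)
        np.testing.assert_allclose(np.abs(r1.t_values), np.abs(r2.t_values), rtol=1e-12)
        np.testing.assert_array_equal(r1.order, r2.order)
        scaled = scores.copy()
        scaled[:, 2] *= 7.5
        r3 = rank_pcs(scaled, labels)
        np.testing.assert_allclose(np.abs(r3.t_values), np.abs(r1.t_values), rtol=1e-10)

    def test_single_class_subset_rejected(self):
        scores = np.zeros((6, 2))
        labels = np.array(["TD"] * 3 + ["ASD"] * 3)
        with pytest.raises(ValueError):
            rank_pcs(scores, labels, subject_subset=[0, 1, 2])


class TestGroupContrast:
    def test_identical_groups_zero_difference(self):
        X = np.tile(np.arange(6.0), (8, 1))
        labels = np.array(["TD"] * 4 + ["ASD"] * 4)
        assert (group_contrast(X, labels)["mean_diff"] == 0).all()

    def test_label_swap_negates_difference(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10, 7))
        labels = np.array(["TD"] * 5 + ["ASD"] * 5)
        d1 = group_contrast(X, labels)["mean_diff"].to_numpy()
        d2 = group_contrast(X, np.where(labels == "TD", "ASD", "TD"))["mean_diff"].to_numpy()
        np.testing.assert_allclose(d1, -d2, atol=1e-12)

    def test_injected_pattern_recovered_by_top_t(self):
        """Channels carrying the injected group difference dominate the
        |t| ranking when the effect far exceeds the noise."""
        rng = np.random.default_rng(1)
        n_ch, support = 20, np.arange(5, 10)
        X = rng.standard_normal((36, n_ch)) * 0.1
        labels = np.array(["TD"] * 19 + ["ASD"] * 17)
        X[np.ix_(labels == "ASD", support)] -= 2.0
        contrast = group_contrast(X, labels)
        top = np.argsort(-np.abs(contrast["t"].to_numpy()))[: support.size]
        assert set(support) <= set(top)
        # TD-minus-ASD convention: ASD reduced => positive difference
        assert (contrast["mean_diff"].to_numpy()[support] > 0).all()


class TestSVMWeightMap:
    def test_single_component_identity(self):
        pca = fit_pca(random_matrix(0), n_pc=4)
        out = svm_weight_map(np.array([1.0]), pca, [2])
        np.testing.assert_allclose(out, pca.components_[2], atol=1e-12)

    def test_orthonormal_norm_pythagoras(self):
        pca = fit_pca(random_matrix(1), n_pc=4)
        out = svm_weight_map(np.array([1.0, -1.0]), pca, [0, 3])
        assert np.linalg.norm(out) == pytest.approx(np.sqrt(2), abs=1e-8)

    def test_projection_round_trip_recovers_weights(self):
        X, labels = simulate_feature_table(10, 10, 12, rng=np.random.default_rng(2))
        pca = fit_pca(X, n_pc=6)
        selected = [1, 4, 5]
        svm = LinearSVM().fit(pca.scores_[:, selected], labels)
        wmap = svm_weight_map(svm, pca, selected)
        back = wmap @ pca.components_[selected].T
        np.testing.assert_allclose(back, svm.coef_[0], atol=1e-8)

    def test_dimension_mismatch_rejected(self):
        pca = fit_pca(random_matrix(3), n_pc=4)
        with pytest.raises(ValueError):
            svm_weight_map(np.array([1.0, 2.0]), pca, [0])


class TestTScoreSelector:
    def test_sklearn_pipeline_reproduces_fast_nested_path(self):
        """The composable sklearn route (selector + standardizing SVM under
        LeaveOneOut) must agree exactly with the compiled nested LOO loop."""
        from sklearn.model_selection import LeaveOneOut
        from sklearn.pipeline import Pipeline

        X, labels = simulate_feature_table(10, 9, 12, rng=np.random.default_rng(5))
        k = 4
        scores_ref = np.empty(len(labels))
        for tr, te in LeaveOneOut().split(X):
            pipe = Pipeline(
                [
                    ("select", TScoreSelector(k=k)),
                    ("svm", LinearSVM(standardize=True)),
                ]
            ).fit(X[tr], labels[tr])
            scores_ref[te[0]] = pipe.decision_function(X[te])[0]
        fast = loo_svm(X, labels, k=k, mode="nested")
        np.testing.assert_allclose(fast.scores, scores_ref, atol=1e-5)

    def test_selects_top_k_by_absolute_t(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((20, 8))
        labels = np.array(["TD"] * 10 + ["ASD"] * 10)
        X[labels == "ASD", 5] += 4.0
        sel = TScoreSelector(k=1).fit(X, labels)
        assert sel.get_support().nonzero()[0].tolist() == [5]
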