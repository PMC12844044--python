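import numpy as np
import pytest

from recovermet.multivariate import (
    ModelError,
    opls_fit,
    opls_permutation_test,
    pca_fit,
    splot_coordinates,
    vip_scores,
)

from oracles import pls1_scores


def _two_class_data(seed=0, n_per=20, p=8, effect=2.0, ortho=0.0):
    """Balanced two-class matrix with a y-correlated direction, optional
    y-orthogonal structured variation, and isotropic noise."""
    rng = np.random.default_rng(seed)
    y = np.array(["a"] * n_per + ["b"] * n_per)
    coded = np.where(y == "b", 1.0, -1.0)
    direction = rng.normal(size=p)
    direction /= np.linalg.norm(direction)
    X = np.outer(coded * effect / 2, direction) + rng.normal(scale=1.0, size=(2 * n_per, p))
    if ortho:
        o_dir = rng.normal(size=p)
        o_dir -= (o_dir @ direction) * direction
        o_dir /= np.linalg.norm(o_dir)
        X += np.outer(rng.normal(scale=ortho, size=2 * n_per), o_dir)
    return X, y


class TestPca:
    def test_rank_one_matrix_explains_everything(self):
        base = np.outer(np.arange(6, dtype=float), [1.0, 2.0, -1.0])
        model = pca_fit(base, 1)
        assert model.explained_variance_fraction.iloc[0] == pytest.approx(1.0)

    def test_explained_fractions_match_eigendecomposition(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 4))
        model = pca_fit(X, 3)
        cov = np.cov(X, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected = eig / eig.sum()
        assert np.allclose(model.explained_variance_fraction, expected[:3], atol=1e-12)

    def test_duplicated_rows_identical_loadings(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 4))
        m1 = pca_fit(X, 2)
        m2 = pca_fit(np.vstack([X, X]), 2)
        assert np.allclose(m1.loadings, m2.loadings, atol=1e-10)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(4)
        model = pca_fit(rng.normal(size=(10, 6)), 4)
        gram = model.loadings.to_numpy().T @ model.loadings.to_numpy()
        assert np.allclose(gram, np.eye(4), atol=1e-8)

    def test_too_many_components_rejected(self):
        with pytest.raises(ModelError, match="n_components"):
            pca_fit(np.zeros((4, 3)), 4)


class TestOplsFit:
    def test_pls1_limit_matches_independent_oracle(self):
        """With no orthogonal components the predictive scores coincide with
        a one-component PLS1 fit from an independent implementation."""
        X, y = _two_class_data(seed=1)
        model = opls_fit(X, y, n_ortho=0, cv_folds=5, seed=0)
        coded = np.where(y == "b", 1.0, -1.0)
        oracle = pls1_scores(X - X.mean(axis=0), coded - coded.mean())
        corr = abs(np.corrcoef(model.t_pred, oracle)[0, 1])
        assert corr > 0.999

    def test_perfectly_determined_response_gives_r2y_one(self):
        y = np.array(["a"] * 8 + ["b"] * 8)
        X = np.column_stack([np.where(y == "b", 1.0, -1.0)])
        model = opls_fit(X, y, n_ortho=0, cv_folds=4, seed=0)
        assert model.r2y == pytest.approx(1.0)

    def test_orthogonal_scores_orthogonal_to_predictive(self):
        X, y = _two_class_data(seed=5, ortho=3.0)
        model = opls_fit(X, y, n_ortho=2, cv_folds=5, seed=0)
        assert model.n_ortho == 2
        for k in range(model.n_ortho):
            assert abs(model.t_pred @ model.t_ortho[:, k]) < 1e-8

    def test_removing_orthogonal_variation_helps_q2(self):
        X, y = _two_class_data(seed=6, effect=1.5, ortho=6.0)
        m0 = opls_fit(X, y, n_ortho=0, cv_folds=5, seed=0)
        m1 = opls_fit(X, y, n_ortho=1, cv_folds=5, seed=0)
        assert m1.q2 > m0.q2

    def test_cv_deterministic_under_seed(self):
        X, y = _two_class_data(seed=7)
        q2s = {opls_fit(X, y, n_ortho=1, cv_folds=5, seed=42).q2 for _ in range(3)}
        assert len(q2s) == 1

    def test_single_class_rejected(self):
        X = np.random.default_rng(8).normal(size=(10, 3))
        with pytest.raises(ModelError, match="two classes"):
            opls_fit(X, ["a"] * 10, n_ortho=0, cv_folds=2)

    def test_class_smaller_than_folds_rejected(self):
        X, y = _two_class_data(seed=9, n_per=4)
        with pytest.raises(ModelError, match="cv_folds"):
            opls_fit(X, y, n_ortho=0, cv_folds=5)


class TestVip:
    def test_single_informative_feature(self):
        """X with one covarying feature and three constants: w = e1 exactly,
        so VIP = sqrt(4) * 1 = 2 there and 0 elsewhere."""
        y = np.array(["a"] * 6 + ["b"] * 6)
        coded = np.where(y == "b", 1.0, -1.0)
        X = np.column_stack([coded, np.zeros(12), np.zeros(12), np.zeros(12)])
        model = opls_fit(X, y, n_ortho=0, cv_folds=3, seed=0)
        assert np.allclose(vip_scores(model).to_numpy(), [2.0, 0.0, 0.0, 0.0])

    def test_symmetric_features_equal_vip(self):
        y = np.array(["a"] * 6 + ["b"] * 6)
        coded = np.where(y == "b", 1.0, -1.0)
        X = np.column_stack([coded, coded, np.zeros(12)])
        model = opls_fit(X, y, n_ortho=0, cv_folds=3, seed=0)
        vip = vip_scores(model)
        assert vip.iloc[0] == pytest.approx(vip.iloc[1])

    def test_mean_square_vip_is_one(self):
        X, y = _two_class_data(seed=10)
        model = opls_fit(X, y, n_ortho=1, cv_folds=5, seed=0)
        assert float((model.vip**2).mean()) == pytest.approx(1.0, abs=1e-8)


class TestPermutation:
    def test_zero_permutations_degenerate_p(self):
        X, y = _two_class_data(seed=11, n_per=8)
        model = opls_fit(X, y, n_ortho=0, cv_folds=4, seed=0)
        record = opls_permutation_test(X, y, n_perm=0, seed=0, cv_folds=4, model=model)
        assert record.p_value == 1.0

    def test_strong_separation_hits_formula_minimum(self):
        """Widely separated classes: no permuted Q2 reaches the observed one,
        so the add-one estimator yields exactly 1/201 at 200 permutations."""
        # n_per large enough that drawing the exact label complement (which
        # reproduces the observed Q2 by sign symmetry) is negligibly likely
        X, y = _two_class_data(seed=12, n_per=12, effect=12.0)
        model = opls_fit(X, y, n_ortho=0, cv_folds=3, seed=0)
        record = opls_permutation_test(X, y, n_perm=200, seed=0, cv_folds=3, model=model)
        assert record.p_value == pytest.approx(1 / 201)


class TestSplot:
    def test_feature_equal_to_score_has_correlation_one(self):
        X, y = _two_class_data(seed=13)
        model = opls_fit(X, y, n_ortho=0, cv_folds=5, seed=0)
        X2 = np.column_stack([X, model.t_pred])
        model2 = opls_fit(X2, y, n_ortho=0, cv_folds=5, seed=0)
        coords = splot_coordinates(model2, X2)
        assert abs(coords["correlation"].iloc[-1]) > 0.999

    def test_covariance_column_matches_loading_identity(self):
        """With no deflation, cov(x_j, t) = p_j * (t't)/(n-1)."""
        X, y = _two_class_data(seed=14)
        model = opls_fit(X, y, n_ortho=0, cv_folds=5, seed=0)
        coords = splot_coordinates(model, X)
        t = model.t_pred
        expected = model.p_pred * (t @ t) / (len(t) - 1)
        assert np.allclose(coords["covariance"], expected, atol=1e-10)

    def test_pure_noise_feature_near_zero_correlation(self):
        rng = np.random.default_rng(15)
        n = 10_000
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        coded = np.where(y == "b", 1.0, -1.0)
        X = np.column_stack([coded + 0.5 * rng.normal(size=n), rng.normal(size=n)])
        model = opls_fit(X, y, n_ortho=0, cv_folds=2, seed=0)
        coords = splot_coordinates(model, X)
        assert abs(coords["correlation"].iloc[1]) < 0.05

    def test_zero_variance_feature_flagged(self):
        X, y = _two_class_data(seed=16)
        X = np.column_stack([X, np.full(len(y), 3.0)])
        model = opls_fit(X, y, n_ortho=0, cv_folds=5, seed=0)
        coords = splot_coordinates(model, X)
        assert bool(coords["zero_variance"].iloc[-1])
        assert coords["correlation"].iloc[-1] == 0.0
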