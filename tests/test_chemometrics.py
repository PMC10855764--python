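"""Tests for autoscaling, PCA, NIPALS PLS-DA and VIP selection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from cheesevoc import (
    Autoscaler,
    PLSDAClassifier,
    PLSRegressionNIPALS,
    PrincipalComponents,
    autoscale,
    confidence_ellipse,
    pca,
    select_markers,
    vip_scores,
)
from cheesevoc.chemometrics import VIPVector, vip_per_class
from cheesevoc.exceptions import DataError, NumericalError


class TestAutoscale:
    def test_two_point_column(self):
        """(1, 3) scales to (-1/sqrt(2), +1/sqrt(2)) under ddof=1."""
        out = autoscale(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(
            out.values.ravel(), [-0.7071067, 0.7071067], atol=1e-6
        )

    def test_idempotence(self, rng):
        X = rng.normal(size=(30, 5)) * 3 + 7
        once = autoscale(X).values
        twice = autoscale(once).values
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_constant_column_zeroed_with_warning(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.warns(UserWarning, match="constant"):
            out = autoscale(X)
        assert (out.values[:, 1] == 0).all()

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            autoscale(np.ones((1, 3)))

    def test_transform_uses_training_parameters(self, rng):
        X = rng.normal(size=(20, 4))
        sc = Autoscaler().fit(X)
        shifted = sc.transform(X + 1.0)
        np.testing.assert_allclose(
            shifted, sc.transform(X) + 1.0 / sc.scale_, atol=1e-12
        )


class TestPCA:
    def test_rank_one_data(self, rng):
        """Two perfectly correlated variables: PC1 explains everything."""
        x = rng.normal(size=50)
        X = autoscale(np.column_stack([x, 2 * x])).values
        with pytest.warns(UserWarning, match="rank"):
            model = PrincipalComponents(n_components=2).fit(X)
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0)
        np.testing.assert_allclose(
            np.abs(model.loadings_[:, 0]), [1 / np.sqrt(2)] * 2, atol=1e-9
        )

    def test_scores_uncorrelated_and_fractions_sum_to_one(self, rng):
        X = autoscale(rng.normal(size=(40, 6))).values
        model = PrincipalComponents(n_components=6).fit(X)
        scores = model.transform(X)
        cov = np.cov(scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8
        assert model.explained_variance_ratio_.sum() == pytest.approx(1.0)
        assert (np.diff(model.explained_variance_ratio_) <= 1e-12).all()

    def test_sign_convention_largest_loading_positive(self, rng):
        X = autoscale(rng.normal(size=(30, 5))).values
        model = PrincipalComponents(n_components=3).fit(X)
        for j in range(3):
            col = model.loadings_[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_isotropic_two_dimensional_data(self, rng):
        X = autoscale(rng.normal(size=(4000, 2))).values
        model = PrincipalComponents(n_components=2).fit(X)
        np.testing.assert_allclose(
            model.explained_variance_ratio_, [0.5, 0.5], atol=0.05
        )

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(DataError):
            PrincipalComponents(n_components=7).fit(rng.normal(size=(20, 6)))


class TestConfidenceEllipse:
    def _circle(self, n=40, r=2.0):
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return r * np.column_stack([np.cos(theta), np.sin(theta)])

    def test_center_of_symmetric_cloud(self):
        ell = confidence_ellipse(self._circle(), label="g")
        np.testing.assert_allclose(ell.center, [0.0, 0.0], atol=1e-9)

    def test_chi_square_quantile_scaling(self):
        """At the 95% level the covariance is scaled by chi2(2) = 5.991."""
        S = self._circle()
        ell = confidence_ellipse(S, level=0.95)
        q = stats.chi2.ppf(0.95, 2)
        assert q == pytest.approx(5.991, abs=5e-4)
        np.testing.assert_allclose(
            ell.shape, np.cov(S, rowvar=False) * q, atol=1e-9
        )

    def test_doubling_scores_doubles_axes(self):
        S = self._circle()
        e1 = confidence_ellipse(S)
        e2 = confidence_ellipse(2 * S)
        np.testing.assert_allclose(e2.shape, 4 * e1.shape, atol=1e-9)

    def test_containment_matches_mahalanobis(self, rng):
        S = rng.normal(size=(200, 2))
        ell = confidence_ellipse(S, level=0.95)
        q = stats.chi2.ppf(0.95, 2)
        inside = 0
        for p in S:
            d = p - ell.center
            md2 = d @ np.linalg.solve(ell.covariance, d)
            assert ell.contains(p) == (md2 <= q)
            inside += ell.contains(p)
        assert 0.85 <= inside / len(S) <= 1.0

    def test_small_or_degenerate_group_rejected(self):
        with pytest.raises(DataError):
            confidence_ellipse(np.zeros((2, 2)))
        with pytest.raises(NumericalError):
            confidence_ellipse(np.tile([1.0, 2.0], (5, 1)))


def _two_clouds(rng, n=20, gap=8.0, p=5):
    X = rng.normal(size=(2 * n, p))
    X[n:, 0] += gap
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestPLSDA:
    def test_separable_clouds_zero_training_error(self, rng):
        X, y = _two_clouds(rng)
        model = PLSDAClassifier(n_components=1).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_null_labels_low_r2y(self, rng):
        """With labels independent of X the training R2Y stays near zero."""
        X = rng.normal(size=(400, 5))
        y = np.array(["a", "b"] * 200)
        model = PLSDAClassifier(n_components=1).fit(X, y)
        yhat = model.decision_function(X)[:, 1]
        ybin = (y == "b").astype(float)
        r2 = 1 - np.sum((ybin - yhat) ** 2) / np.sum((ybin - 0.5) ** 2)
        assert r2 < 0.05

    def test_single_informative_column_concentrates_weight(self, rng):
        X = rng.normal(size=(60, 10)) * 0.01
        y = np.array(["a", "b"] * 30)
        X[:, 4] += (y == "b") * 5.0
        model = PLSDAClassifier(n_components=1).fit(X, y)
        w = np.abs(model.pls_.x_weights_[:, 0])
        assert np.argmax(w) == 4
        assert w[4] > 0.95

    def test_midpoint_of_symmetric_classes_scores_half(self, rng):
        X, y = _two_clouds(rng, n=50, gap=6.0)
        model = PLSDAClassifier(n_components=1).fit(X, y)
        mid = 0.5 * (X[y == "a"].mean(axis=0) + X[y == "b"].mean(axis=0))
        score = model.decision_function(mid[None, :])[0, 1]
        assert score == pytest.approx(0.5, abs=0.05)

    def test_duplicated_point_identical_prediction(self, rng):
        X, y = _two_clouds(rng)
        model = PLSDAClassifier(n_components=2).fit(X, y)
        two = np.vstack([X[3], X[3]])
        d = model.decision_function(two)
        np.testing.assert_array_equal(d[0], d[1])

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(DataError):
            PLSDAClassifier().fit(X, np.array(["a"] * 10))

    def test_score_orthogonality(self, rng):
        X, y = _two_clouds(rng, p=8)
        model = PLSDAClassifier(n_components=4).fit(X, y)
        T = model.pls_.x_scores_
        G = T.T @ T
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8

    def test_full_rank_pls_matches_ols(self, rng):
        """With A = rank(X), PLS reproduces the least-squares fit."""
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        m = PLSRegressionNIPALS(n_components=6, scale=False).fit(
            X - X.mean(0), y - y.mean()
        )
        Xc = X - X.mean(0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        np.testing.assert_allclose(
            m.predict(Xc) + y.mean() - y.mean(), Xc @ beta, atol=1e-8
        )

    def test_matches_sklearn_pls2_under_identical_preprocessing(self, rng):
        X = rng.normal(size=(50, 12))
        Y = np.column_stack(
            [X[:, 0] + 0.1 * rng.normal(size=50), X[:, 5] + 0.1 * rng.normal(size=50)]
        )
        Xs = Autoscaler().fit(X).transform(X)
        Yc = Y - Y.mean(axis=0)
        mine = PLSRegressionNIPALS(n_components=3, scale=False).fit(Xs, Yc)
        ref = PLSRegression(
            n_components=3, scale=False, tol=1e-12, max_iter=5000
        ).fit(Xs, Yc)
        np.testing.assert_allclose(
            mine.predict(Xs), ref.predict(Xs), atol=1e-5
        )

    def test_prediction_rules_agree_on_well_separated_binary(self, rng):
        X, y = _two_clouds(rng, gap=10.0)
        preds = {}
        for rule in ("mahalanobis", "centroid", "indicator"):
            m = PLSDAClassifier(n_components=2, prediction_rule=rule).fit(X, y)
            preds[rule] = m.predict(X)
        for rule, p in preds.items():
            assert (p == y).all(), rule

    def test_deflation_identity(self, rng):
        """X is reconstructed from scores and loadings plus the residual."""
        X, y = _two_clouds(rng, p=4)
        m = PLSDAClassifier(n_components=4, scale=True).fit(X, y)
        pls = m.pls_
        Xs = pls.scaler_.transform(X) if pls.scaler_ else X
        recon = pls.x_scores_ @ pls.x_loadings_.T
        resid = Xs - recon
        # residual orthogonal to extracted scores
        assert np.abs(pls.x_scores_.T @ resid).max() < 1e-8


class TestVIP:
    def test_identical_copies_all_vip_one(self, rng):
        signal = rng.normal(size=80)
        X = np.tile(signal[:, None], (1, 6)) + rng.normal(size=(80, 6)) * 1e-9
        y = (signal > 0).astype(float)
        m = PLSRegressionNIPALS(n_components=1, scale=True).fit(X, y)
        v = vip_scores(m)
        np.testing.assert_allclose(v.scores, np.ones(6), atol=1e-4)

    def test_single_informative_variable_vip_sqrt_p(self, rng):
        p = 9
        y = rng.normal(size=100)
        yc = y - y.mean()
        X = rng.normal(size=(100, p))
        # uninformative columns exactly orthogonal to the response
        X -= np.outer(yc, yc @ X) / (yc @ yc)
        X[:, 2] = y  # the one noiseless informative column
        m = PLSRegressionNIPALS(n_components=1, scale=True).fit(X, y)
        v = vip_scores(m)
        assert v.scores[2] == pytest.approx(np.sqrt(p), rel=1e-6)
        assert np.delete(v.scores, 2).max() < 1e-6

    @given(seed=st.integers(0, 1000), n_lv=st.integers(1, 4))
    def test_mean_squared_vip_is_one(self, seed, n_lv):
        """Sum of squared VIPs equals the variable count on any fit."""
        r = np.random.default_rng(seed)
        X = r.normal(size=(30, 7))
        y = r.normal(size=30) + X[:, 0]
        m = PLSRegressionNIPALS(n_components=n_lv, scale=True).fit(X, y)
        v = vip_scores(m)
        assert (v.scores**2).sum() == pytest.approx(7.0, abs=1e-6)

    def test_multiclass_per_class_vip_normalized(self, camembert_table):
        X = camembert_table.data.to_numpy()
        y = camembert_table.doses.to_numpy()
        m = PLSDAClassifier(n_components=3).fit(X, y)
        per = vip_per_class(m, variable_names=camembert_table.data.columns)
        assert set(per) == set(np.unique(y))
        for v in per.values():
            assert (v.scores**2).sum() == pytest.approx(79.0, abs=1e-6)

    def test_selection_threshold_inclusive_and_sorted(self):
        v = VIPVector(
            scores=np.array([1.5, 1.2, 0.9]),
            variable_names=("a", "b", "c"),
        )
        assert select_markers(v, 1.2) == ["a", "b"]
        assert select_markers(v, 2.0) == []
        with pytest.raises(DataError):
            select_markers(v, 0.0)


def test_functional_wrappers(camembert_table):
    """pca/fit_plsda wrappers behave like the estimators they wrap."""
    X = autoscale(camembert_table.data.to_numpy()).values
    model = pca(X, n_components=2)
    assert model.transform(X).shape == (90, 2)
    from cheesevoc.chemometrics import fit_plsda, predict_plsda

    clf = fit_plsda(X, camembert_table.doses.to_numpy(), n_lv=2)
    scores, hard = predict_plsda(clf, X)
    assert scores.shape == (90, 4)
    assert set(hard) <= set(camembert_table.doses)
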