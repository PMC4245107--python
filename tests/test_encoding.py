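import numpy as np
import pytest

import storyenc as se
from storyenc.design import DesignMatrix
from storyenc.stimulus import FeatureTimeSeries


def _design(values, n_lags=1, tr=2.0):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    F = values.shape[1] // n_lags
    return DesignMatrix(values, n_lags=n_lags, tr=tr,
                        feature_names=[f"f{i}" for i in range(F)])


class TestRidgeWorkedExamples:
    def test_unpenalized_slope(self):
        X = _design([[1.0], [2.0]])
        res = se.fit_ridge(X, np.array([[2.0], [4.0]]), penalty_grid=[0.0],
                           standardize=False)
        np.testing.assert_allclose(res.weights, [[2.0]], atol=1e-10)

    def test_penalty_two_shrinks_to_ten_sevenths(self):
        X = _design([[1.0], [2.0]])
        res = se.fit_ridge(X, np.array([[2.0], [4.0]]), penalty_grid=[2.0],
                           standardize=False)
        np.testing.assert_allclose(res.weights, [[10.0 / 7.0]], atol=1e-10)

    def test_huge_penalty_annihilates_weights(self):
        rng = np.random.default_rng(0)
        X = _design(rng.normal(size=(30, 4)), n_lags=2)
        Y = rng.normal(size=(30, 3))
        res = se.fit_ridge(X, Y, penalty_grid=[1e12])
        assert np.max(np.abs(res.weights)) < 1e-6

    def test_all_zero_feature_column_gets_zero_weight(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(30, 2))
        vals[:, 1] = 0.0
        X = _design(vals, n_lags=1)
        Y = rng.normal(size=(30, 2))
        res = se.fit_ridge(X, Y, penalty_grid=[5.0])
        np.testing.assert_allclose(res.weights[:, 1], 0.0, atol=1e-12)


class TestRidgeOracleEquivalence:
    def test_matches_direct_normal_equations_on_random_problems(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            T = int(rng.integers(10, 31))
            P = int(rng.integers(1, 9))
            lam = float(rng.uniform(0.1, 100))
            X = _design(rng.normal(size=(T, P)), n_lags=1)
            Y = rng.normal(size=(T, 2))
            res = se.fit_ridge(X, Y, penalty_grid=[lam], standardize=False)
            direct = np.linalg.solve(
                X.values.T @ X.values + lam * np.eye(P), X.values.T @ Y).T
            np.testing.assert_allclose(res.weights, direct, atol=1e-8)

    def test_shrinkage_is_monotone_in_penalty(self):
        rng = np.random.default_rng(7)
        X = _design(rng.normal(size=(40, 6)), n_lags=2)
        Y = rng.normal(size=(40, 3))
        norms = []
        for lam in [0.1, 1, 10, 100, 1e4]:
            res = se.fit_ridge(X, Y, penalty_grid=[lam], standardize=False)
            norms.append(np.linalg.norm(res.weights))
        assert all(a >= b for a, b in zip(norms, norms[1:]))


class TestPredict:
    def test_standardized_zero_design_predicts_voxel_means(self):
        rng = np.random.default_rng(2)
        X = _design(rng.normal(size=(50, 3)), n_lags=1)
        Y = rng.normal(10, 2, size=(50, 4))
        res = se.fit_ridge(X, Y, penalty_grid=[1.0])
        at_means = _design(np.tile(X.values.mean(axis=0), (5, 1)), n_lags=1)
        pred = res.predict(at_means, scale="original")
        np.testing.assert_allclose(pred, np.tile(Y.mean(axis=0), (5, 1)),
                                   atol=1e-8)

    def test_interpolation_limit_reproduces_training_data(self):
        rng = np.random.default_rng(3)
        T = 6
        X = _design(rng.normal(size=(T, T)), n_lags=2)
        Y = rng.normal(size=(T, 2))
        res = se.fit_ridge(X, Y, penalty_grid=[0.0], standardize=False)
        np.testing.assert_allclose(res.predict(X), Y, atol=1e-8)

    def test_single_lagged_weight_echoes_impulse(self):
        # one feature, one lag, w = 2: an impulse at t=0 contributes at t=1
        fts = FeatureTimeSeries(np.array([[0.0], [1.0], [0.0]]).T.reshape(3, 1),
                                tr=2.0, feature_names=["f0"])
        fts.values[:] = [[0.0], [1.0], [0.0]]
        X = se.build_lagged_design(fts, n_lags=1)
        res = se.fit_ridge(X, 2.0 * X.values, penalty_grid=[0.0],
                           standardize=False)
        np.testing.assert_allclose(res.predict(X)[:, 0], [0.0, 0.0, 2.0],
                                   atol=1e-10)

    def test_column_mismatch_names_offenders(self):
        rng = np.random.default_rng(4)
        X = _design(rng.normal(size=(20, 2)), n_lags=1)
        res = se.fit_ridge(X, rng.normal(size=(20, 1)), penalty_grid=[1.0])
        other = DesignMatrix(rng.normal(size=(20, 2)), n_lags=1, tr=2.0,
                             feature_names=["g0", "g1"])
        with pytest.raises(ValueError, match="column"):
            res.predict(other)


class TestSignatures:
    def test_signature_ordered_by_lag(self):
        rng = np.random.default_rng(5)
        fts = FeatureTimeSeries(rng.normal(size=(200, 2)), tr=2.0,
                                feature_names=["a", "b"])
        X = se.build_lagged_design(fts, n_lags=4)
        true_sig = np.array([0.2, 1.0, 0.7, 0.1])
        W = np.zeros((1, 8))
        W[0, 4:] = 2.0 * true_sig       # feature "b", lags 1..4
        Y = X.values @ W.T
        res = se.fit_ridge(X, Y, penalty_grid=[1e-6])
        curve = res.extract_signature(0, "b")
        np.testing.assert_allclose(curve, 2.0 * true_sig, atol=1e-4)
        assert res.extract_signature(0, "a") == pytest.approx([0] * 4,
                                                              abs=1e-6)

    def test_noisy_recovery_correlates_with_truth(self):
        story, subjects, truth = se.default_scenario(
            seed=9, snr=1.0, T=1000, n_voxels=50, n_subjects=1,
            n_features=10, layout={"semantics": 0.4})
        fts = se.resample_to_tr(story, 2.0)
        fts.values = fts.values[:1000]
        X = se.build_lagged_design(fts, n_lags=4)
        res = se.fit_ridge(X, subjects[0].fmri)
        driven = truth.driven_voxels
        cols = [story.feature_names.index(m)
                for m in story.feature_sets["semantics"]]
        sub = np.ix_(driven, cols)
        w_true = truth.weights[0][sub].ravel()
        w_est = res.signatures("original")[sub].ravel()
        assert np.corrcoef(w_true, w_est)[0, 1] > 0.95

    def test_unknown_feature_rejected(self):
        rng = np.random.default_rng(6)
        X = _design(rng.normal(size=(20, 2)), n_lags=2)
        res = se.fit_ridge(X, rng.normal(size=(20, 1)), penalty_grid=[1.0])
        with pytest.raises(KeyError):
            res.extract_signature(0, "nope")


class TestPenaltySelection:
    def test_noise_voxels_get_penalties_near_top_of_grid(self):
        story, subjects, _ = se.default_scenario(
            seed=6, snr=0.0, T=600, n_voxels=100, n_subjects=1,
            n_features=10)
        fts = se.resample_to_tr(story, 2.0)
        fts.values = fts.values[:600]
        X = se.build_lagged_design(fts, n_lags=4)
        res = se.fit_ridge(X, subjects[0].fmri)
        grid = se.DEFAULT_PENALTY_GRID
        assert np.mean(res.penalties >= grid[-2]) >= 0.9

    def test_summary_mentions_dimensions(self, small_dataset):
        story, subjects, _ = small_dataset
        fts = se.resample_to_tr(story, 2.0)
        fts.values = fts.values[:subjects[0].n_trs]
        X = se.build_lagged_design(fts, n_lags=4)
        res = se.fit_ridge(X, subjects[0].fmri)
        text = res.summary()
        assert "voxels" in text and "50" in text


class TestFitValidation:
    def test_nan_rejected(self):
        X = _design([[1.0], [np.nan]])
        with pytest.raises(ValueError, match="NaN"):
            se.fit_ridge(X, np.array([[1.0], [2.0]]), penalty_grid=[1.0])

    def test_too_few_rows_for_inner_folds(self):
        X = _design([[1.0], [2.0], [3.0]])
        with pytest.raises(ValueError):
            se.fit_ridge(X, np.zeros((3, 1)), penalty_grid=[1.0, 2.0],
                         inner_folds=5)

    def test_negative_penalty_rejected(self):
        X = _design([[1.0], [2.0]])
        with pytest.raises(ValueError):
            se.fit_ridge(X, np.zeros((2, 1)), penalty_grid=[-1.0])
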