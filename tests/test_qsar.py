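"""SVR QSAR machinery: validation statistics, prediction, applicability."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.dummy import DummyRegressor
from sklearn.linear_model import LinearRegression

from simplihit import qsar


class TestLooQ2:
    def test_mean_predictor_hand_computed(self):
        # y = (1,2,3,4); leaving each out, the mean of the rest predicts it:
        # PRESS = 4 + 4/9 + 4/9 + 4 = 80/9, SS_tot = 5 -> Q2 = 1 - 16/9 = -7/9
        y = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.zeros((4, 1))
        q2 = qsar.loo_q2(DummyRegressor(strategy="mean"), X, y)
        assert q2 == pytest.approx(-7 / 9)

    def test_global_mean_predictions_give_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.zeros((4, 1))
        q2 = qsar.loo_q2(DummyRegressor(strategy="constant", constant=y.mean()), X, y)
        assert q2 == pytest.approx(0.0)

    def test_perfect_predictions_give_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 1))
        y = 3.0 * X[:, 0] + 1.0  # exactly linear, LOO fits recover it
        assert qsar.loo_q2(LinearRegression(), X, y) == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(qsar.QSARError):
            qsar.loo_q2(LinearRegression(), np.zeros((4, 1)), np.ones(4))
        with pytest.raises(qsar.QSARError):
            qsar.loo_q2(LinearRegression(), np.zeros((2, 1)), np.array([1.0, 2.0]))


class TestKfoldR2:
    def test_k_equal_n_reduces_to_loo(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 2))
        y = X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.1, 12)
        assert qsar.kfold_r2(LinearRegression(), X, y, k=12, seed=0) == pytest.approx(
            qsar.loo_q2(LinearRegression(), X, y)
        )

    def test_perfect_model_scores_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 1))
        y = 2.0 * X[:, 0]
        assert qsar.kfold_r2(LinearRegression(), X, y, k=5, seed=0) == pytest.approx(1.0)

    def test_matches_independent_fold_reimplementation(self):
        # brute-force the quantile-stratified split + pooled R2 for one
        # fixed tiny dataset and seed
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 2))
        y = X[:, 0] + rng.normal(0, 0.3, 10)
        k, seed = 3, 42
        order = np.argsort(y, kind="mergesort")
        gen = np.random.default_rng(seed)
        folds = np.empty(10, dtype=int)
        for start in range(0, 10, k):
            block = order[start : start + k].copy()
            gen.shuffle(block)
            folds[block] = np.arange(len(block))
        preds = np.empty(10)
        for fold in range(k):
            test = folds == fold
            m = LinearRegression().fit(X[~test], y[~test])
            preds[test] = m.predict(X[test])
        expected = 1 - np.sum((y - preds) ** 2) / np.sum((y - y.mean()) ** 2)
        assert qsar.kfold_r2(LinearRegression(), X, y, k=k, seed=seed) == pytest.approx(expected)

    def test_too_many_folds_rejected(self):
        with pytest.raises(qsar.QSARError, match="exceeds"):
            qsar.kfold_r2(LinearRegression(), np.zeros((4, 1)), np.arange(4.0), k=5)


class TestGridSearchTrain:
    def test_linear_signal_is_learnable(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"x": rng.normal(size=60)})
        y = 2.0 * X["x"].to_numpy() + 5.0
        model = qsar.grid_search_train(X, y, target_name="t", cv_seed=4)
        assert model.cv_r2 > 0.95

    def test_pure_noise_is_unlearnable(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        scores = []
        for seed in range(3):
            y = np.random.default_rng(100 + seed).normal(size=60)
            scores.append(qsar.grid_search_train(X, y, cv_seed=seed).cv_r2)
        assert np.mean(scores) <= 0.2

    def test_degenerate_y_rejected(self):
        X = pd.DataFrame({"x": np.arange(30.0)})
        with pytest.raises(qsar.QSARError):
            qsar.grid_search_train(X, np.ones(30))

    def test_small_n_rejected(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(qsar.QSARError, match="20"):
            qsar.grid_search_train(X, np.arange(10.0))

    def test_persistence_roundtrip(self, tmp_path):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = X["a"].to_numpy() + rng.normal(0, 0.1, 30)
        model = qsar.grid_search_train(X, y, target_name="t", cv_seed=6)
        model.save(tmp_path / "model_t")
        loaded = qsar.QSARModel.load(tmp_path / "model_t")
        assert loaded.selected_features == model.selected_features
        assert loaded.training_ranges == model.training_ranges
        np.testing.assert_allclose(qsar.predict(loaded, X), qsar.predict(model, X))


class TestYRandomization:
    @staticmethod
    def _informative(seed=7, n=60):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4))
        y = X[:, 0] + X[:, 1] + rng.normal(0, 0.2, n)
        return X, y

    def test_identity_permutation_equals_unpermuted_score(self):
        X, y = self._informative()
        result = qsar.y_randomization(
            qsar.make_svr(), X, y, n_reps=1, seed=0, permutations=[np.arange(len(y))]
        )
        assert result.mean == pytest.approx(qsar.kfold_r2(qsar.make_svr(), X, y, 5, seed=0))

    def test_seeded_runs_are_identical(self):
        X, y = self._informative()
        a = qsar.y_randomization(qsar.make_svr(), X, y, n_reps=3, seed=9)
        b = qsar.y_randomization(qsar.make_svr(), X, y, n_reps=3, seed=9)
        assert a.scores == b.scores

    def test_informative_data_scores_at_or_below_zero(self):
        X, y = self._informative()
        result = qsar.y_randomization(qsar.make_svr(), X, y, n_reps=20, seed=1)
        assert result.mean <= 0.0


class TestPredictAndExtrapolation:
    @staticmethod
    def _model(seed=8):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.uniform(0, 1, size=(40, 2)), columns=["a", "b"])
        y = X["a"].to_numpy() + rng.normal(0, 0.05, 40)
        return qsar.grid_search_train(X, y, target_name="t", cv_seed=seed), X, y

    def test_duplicate_rows_duplicate_predictions(self):
        model, X, _ = self._model()
        doubled = pd.concat([X.iloc[[0]], X.iloc[[0]]])
        preds = qsar.predict(model, doubled)
        assert preds[0] == preds[1]

    def test_missing_feature_column_is_schema_error(self):
        model, X, _ = self._model()
        with pytest.raises(qsar.QSARError, match="'b'"):
            qsar.predict(model, X[["a"]])

    def test_inside_ranges_not_flagged(self):
        model, X, _ = self._model()
        assert not qsar.flag_extrapolation(model, X).any()

    def test_boundary_is_inside_epsilon_beyond_is_outside(self):
        model, X, _ = self._model()
        lo_a, hi_a = model.training_ranges["a"]
        probe = pd.DataFrame({"a": [hi_a, hi_a + 1e-6], "b": [X["b"].iloc[0]] * 2})
        flags = qsar.flag_extrapolation(model, probe)
        assert flags.tolist() == [False, True]

    def test_flagging_is_monotone_under_range_widening(self):
        model, X, _ = self._model()
        probe = X.copy()
        probe.loc[:, "a"] = probe["a"] + 2.0  # push everything outside
        before = qsar.flag_extrapolation(model, probe)
        model.training_ranges["a"] = (-100.0, 100.0)
        after = qsar.flag_extrapolation(model, probe)
        assert not (after & ~before).any()

    def test_prediction_records_carry_mean(self):
        model, X, _ = self._model()
        records = qsar.make_prediction_records({"t1": model, "t2": model}, X, X.index)
        for rec in records:
            assert rec.mean_pic50 == pytest.approx(
                (rec.predictions["t1"] + rec.predictions["t2"]) / 2
            )


class TestSpearman:
    def test_identity_and_reversal(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert qsar.spearman(x, x) == pytest.approx(1.0)
        assert qsar.spearman(x, list(reversed(x))) == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        # ranks differ by d = (-2, 1, 1, -1, 1), sum d^2 = 8:
        # rho = 1 - 6*8 / (5*24) = 0.6
        assert qsar.spearman([1, 2, 3, 4, 5], [3, 1, 2, 5, 4]) == pytest.approx(0.6)

    def test_constant_vector_rejected(self):
        with pytest.raises(qsar.QSARError, match="constant"):
            qsar.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(qsar.QSARError):
            qsar.spearman([1.0, 2.0], [1.0, 2.0, 3.0])


class TestParameterRecovery:
    def test_q2_approaches_one_with_noise_free_data(self):
        # a smooth SVR-representable function, no noise: Q2 improves with n
        def dataset(n, seed):
            rng = np.random.default_rng(seed)
            X = rng.uniform(-1, 1, size=(n, 2))
            y = np.sin(2 * X[:, 0]) + X[:, 1] ** 2
            return X, y

        spec = qsar.make_svr(C=100.0, gamma=1.0, epsilon=0.01)
        X_small, y_small = dataset(50, 10)
        X_large, y_large = dataset(200, 10)
        q2_small = qsar.loo_q2(spec, X_small, y_small)
        q2_large = qsar.loo_q2(spec, X_large, y_large)
        assert q2_large > q2_small
        assert q2_large > 0.99
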