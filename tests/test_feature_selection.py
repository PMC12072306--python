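"""Hybrid CFE/RFE/RFA feature selection."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LinearRegression

from simplihit import qsar
from simplihit.feature_selection import (
    SelectionConfig,
    cfe,
    hybrid_select,
    rfa,
    rfe,
    _cv_score,
)


def _feature_with_exact_correlation(y: np.ndarray, r: float, seed: int) -> np.ndarray:
    """x whose sample Pearson correlation with y is exactly r."""
    rng = np.random.default_rng(seed)
    yc = (y - y.mean()) / np.linalg.norm(y - y.mean())
    z = rng.normal(size=len(y))
    z = z - z.mean()
    z -= (z @ yc) * yc  # orthogonalise against y
    z /= np.linalg.norm(z)
    return r * yc + np.sqrt(1 - r**2) * z


class TestCFE:
    def test_threshold_is_a_sharp_cut(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=60)
        X = pd.DataFrame({
            "just_above": _feature_with_exact_correlation(y, 0.31, 1),
            "just_below": _feature_with_exact_correlation(y, 0.29, 2),
        })
        kept, removed = cfe(X, y, 0.3)
        assert kept == ["just_above"]
        assert removed == ["just_below"]

    def test_sign_symmetry(self):
        y = np.arange(10.0)
        X = pd.DataFrame({"pos": y.copy(), "neg": -y})
        kept, _ = cfe(X, y, 0.3)
        assert kept == ["pos", "neg"]  # |r| = 1 both ways

    def test_constant_feature_counts_as_zero_correlation(self):
        y = np.arange(10.0)
        X = pd.DataFrame({"const": np.ones(10), "good": y.copy()})
        kept, removed = cfe(X, y, 0.3)
        assert removed == ["const"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(Exception, match="3 samples"):
            cfe(pd.DataFrame({"a": [1.0, 2.0]}), np.array([1.0, 2.0]))


def _linear_factory():
    return LinearRegression()


class TestRFE:
    def test_noise_features_removed_informative_kept(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(80, 4)), columns=["A", "B", "C", "D"])
        y = X["A"].to_numpy() + X["B"].to_numpy() + rng.normal(0, 0.1, 80)
        config = SelectionConfig(cv_seed=5)
        survivors, removed = rfe(list(X.columns), X, y, qsar.make_svr, config)
        assert sorted(survivors) == ["A", "B"]
        # oracle: exhaustive subset scoring confirms {A, B} is the optimum
        best_subset, best_score = None, -np.inf
        for size in (2, 3, 4):
            for subset in itertools.combinations(X.columns, size):
                s = _cv_score(qsar.make_svr, X, y, list(subset), config)
                if s > best_score:
                    best_subset, best_score = subset, s
        assert sorted(best_subset) == sorted(survivors)

    def test_equal_improvements_break_ties_towards_earliest_column(self, monkeypatch):
        # a stub scorer under which every removal improves by the same
        # amount: the documented tie-break must pick the earliest column
        # each pass, down to the two-feature floor
        import simplihit.feature_selection as fs

        monkeypatch.setattr(
            fs, "_cv_score", lambda mf, X, y, features, config: -0.1 * len(features)
        )
        X = pd.DataFrame(np.zeros((10, 5)), columns=list("vwxyz"))
        survivors, removed = fs.rfe(
            list(X.columns), X, np.arange(10.0), _linear_factory, SelectionConfig()
        )
        assert removed == ["v", "w", "x"]
        assert survivors == ["y", "z"]  # floor respected

    def test_harmless_exact_duplicate_is_not_forced_out(self):
        # removing an exact copy of the only informative feature does not
        # strictly improve the CV score, so the improvement-only rule
        # keeps both — redundancy alone is not grounds for removal
        rng = np.random.default_rng(6)
        x = rng.normal(size=100)
        X = pd.DataFrame({"orig": x, "copy": x.copy(), "noise": rng.normal(size=100)})
        y = x + rng.normal(0, 0.05, 100)
        survivors, removed = rfe(
            list(X.columns), X, y, qsar.make_svr, SelectionConfig(cv_seed=6)
        )
        assert "noise" in removed
        assert {"orig", "copy"} <= set(survivors)

    def test_pure_noise_terminates_with_floor(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("abcdef"))
        y = rng.normal(size=40)
        survivors, removed = rfe(list(X.columns), X, y, _linear_factory, SelectionConfig(cv_seed=7))
        assert len(survivors) >= 2
        assert len(survivors) + len(removed) == 6


class TestRFA:
    def test_nonlinear_feature_missed_by_cfe_is_readded(self):
        # y = x^2 with x symmetric about 0: Pearson r ~ 0 but an RBF-SVR
        # exploits it immediately
        rng = np.random.default_rng(8)
        x = np.linspace(-2, 2, 120) + rng.normal(0, 0.01, 120)
        X = pd.DataFrame({"linear": rng.normal(size=120), "squared_input": x})
        y = x**2 + rng.normal(0, 0.05, 120)
        kept, removed = cfe(X, y, 0.3)
        assert "squared_input" in removed
        final, added = rfa(
            ["squared_input"], ["linear"], X, y, qsar.make_svr, SelectionConfig(cv_seed=8)
        )
        assert added == ["squared_input"]

    def test_noise_candidate_not_added(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({
            "signal": rng.normal(size=100),
            "junk": rng.normal(size=100),
        })
        y = 2 * X["signal"].to_numpy() + rng.normal(0, 0.1, 100)
        final, added = rfa(["junk"], ["signal"], X, y, _linear_factory, SelectionConfig(cv_seed=9))
        assert added == []

    def test_empty_candidate_list_is_identity(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        final, added = rfa([], ["a"], X, np.arange(10.0), _linear_factory)
        assert final == ["a"] and added == []

    def test_overlapping_candidates_rejected(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(Exception, match="overlap"):
            rfa(["a"], ["a"], X, np.arange(10.0), _linear_factory)


class TestHybridSelect:
    def test_single_feature_matrix_selects_it(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=30)
        X = pd.DataFrame({"only": x})
        result = hybrid_select(X, 2 * x, _linear_factory, SelectionConfig(cv_seed=10))
        assert result.selected == ["only"]

    def test_deterministic_given_config(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(60, 8)), columns=[f"f{j}" for j in range(8)])
        y = X["f0"].to_numpy() + X["f3"].to_numpy() + rng.normal(0, 0.2, 60)
        config = SelectionConfig(cv_seed=12)
        a = hybrid_select(X, y, _linear_factory, config)
        b = hybrid_select(X, y, _linear_factory, config)
        assert a == b

    def test_final_score_not_worse_than_post_cfe(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.normal(size=(80, 10)), columns=[f"f{j}" for j in range(10)])
        y = X["f1"].to_numpy() - X["f2"].to_numpy() + rng.normal(0, 0.3, 80)
        config = SelectionConfig(cv_seed=13)
        result = hybrid_select(X, y, _linear_factory, config)
        post_cfe, _ = cfe(X, y, config.cfe_threshold)
        if post_cfe:
            assert (
                _cv_score(_linear_factory, X, y, result.selected, config)
                >= _cv_score(_linear_factory, X, y, post_cfe, config) - 1e-9
            )

    def test_score_trace_monotone_over_accepted_steps(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.normal(size=(70, 8)), columns=[f"f{j}" for j in range(8)])
        y = X["f0"].to_numpy() + 0.5 * X["f5"].to_numpy() + rng.normal(0, 0.2, 70)
        result = hybrid_select(X, y, _linear_factory, SelectionConfig(cv_seed=14))
        scores = [s for _, _, s in result.score_trace]
        assert scores == sorted(scores)

    def test_bookkeeping_partition(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.normal(size=(60, 6)), columns=[f"f{j}" for j in range(6)])
        y = X["f2"].to_numpy() + rng.normal(0, 0.2, 60)
        result = hybrid_select(X, y, _linear_factory, SelectionConfig(cv_seed=15))
        removed = set(result.removed_by_cfe) | set(result.removed_by_rfe)
        # selected and removed only overlap on RFA re-additions
        assert set(result.selected) & removed == set(result.readded_by_rfa)

    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(16)
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        y = X["a"].to_numpy() + rng.normal(0, 0.1, 40)
        result = hybrid_select(X, y, _linear_factory, SelectionConfig(cv_seed=16))
        result.to_json(tmp_path / "sel.json")
        from simplihit.feature_selection import FeatureSelectionResult

        assert FeatureSelectionResult.from_json(tmp_path / "sel.json") == result
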