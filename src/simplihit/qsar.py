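"""Per-target SVM-regression QSAR models: tuning, validation, prediction
and range-based applicability checks.

Each target gets its own model: an RBF-kernel support vector regression on
z-scored descriptors, with hyperparameters chosen by exhaustive grid search
over a seeded 5-fold cross-validation.  Model quality is reported as the
classical QSAR panel — R^2 on the training fit, leave-one-out Q^2, pooled
5- and 10-fold R^2, and the mean score after y-randomization (label
permutation), which should fall to zero or below for an informative model.

Predictions outside the per-feature training (min, max) ranges are flagged
as extrapolations but not removed; the flag travels with the record.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import KFold, LeaveOneOut, ParameterGrid, cross_val_score
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR


class QSARError(ValueError):
    pass


#: Default hyperparameter grid: cost, RBF kernel width, epsilon-tube width.
DEFAULT_GRID: dict[str, list] = {
    "svr__C": [0.1, 1.0, 10.0, 100.0],
    "svr__gamma": [1e-3, 1e-2, 1e-1, 1.0],
    "svr__epsilon": [0.01, 0.1],
}


def make_svr(C: float = 10.0, gamma: float | str = "scale", epsilon: float = 0.1) -> Pipeline:
    """Fresh z-score + RBF-SVR pipeline (the model family used throughout)."""
    return Pipeline(
        [("scaler", StandardScaler()), ("svr", SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon))]
    )


@dataclass
class QSARModel:
    """A fitted per-target model plus everything needed to apply it honestly:
    the selected feature list, frozen scaling statistics, the winning
    hyperparameters, per-feature training ranges for the applicability
    domain, and a fingerprint of the training data."""

    target_name: str
    selected_features: list[str]
    scaler_mean: dict[str, float]
    scaler_sd: dict[str, float]
    hyperparameters: dict[str, float]
    training_ranges: dict[str, tuple[float, float]]
    training_fingerprint: str
    estimator: Pipeline | None = None
    cv_r2: float = float("nan")

    def __post_init__(self) -> None:
        missing = set(self.selected_features) - set(self.training_ranges)
        if missing:
            raise QSARError(f"features without training ranges: {sorted(missing)}")
        bad = [f for f, s in self.scaler_sd.items() if not s > 0]
        if bad:
            raise QSARError(f"zero-variance features cannot be scaled: {bad}")

    def save(self, path_prefix: str | Path) -> None:
        """Persist as JSON metadata + a native estimator artifact."""
        prefix = Path(path_prefix)
        meta = {
            k: v
            for k, v in asdict(self).items()
            if k != "estimator"
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        joblib.dump(self.estimator, prefix.with_suffix(".joblib"))

    @classmethod
    def load(cls, path_prefix: str | Path) -> "QSARModel":
        prefix = Path(path_prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        meta["training_ranges"] = {k: tuple(v) for k, v in meta["training_ranges"].items()}
        est = joblib.load(prefix.with_suffix(".joblib"))
        return cls(estimator=est, **meta)


@dataclass
class ValidationReport:
    """The standard QSAR validation panel for one target."""

    target_name: str
    r2_self: float
    q2_loo: float
    r2_cv5: float
    r2_cv10: float
    y_rand_mean: float
    y_rand_reps: int
    n_features: int

    def warnings(self) -> list[str]:
        out = []
        if self.q2_loo > self.r2_self:
            out.append(f"Q2 ({self.q2_loo:.3f}) exceeds training R2 ({self.r2_self:.3f})")
        return out


@dataclass
class PredictionRecord:
    """Per-molecule dual-target prediction with extrapolation flags."""

    molecule_id: str
    predictions: dict[str, float]  # target -> predicted pIC50
    extrapolated: dict[str, bool]
    mean_pic50: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_pic50 = float(np.mean(list(self.predictions.values())))


def _data_fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=float).tobytes())
    h.update(np.ascontiguousarray(y, dtype=float).tobytes())
    return h.hexdigest()[:16]


def _check_xy(X: pd.DataFrame, y: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise QSARError("X and y have different lengths")
    if np.var(y) == 0:
        raise QSARError("activity vector has zero variance")
    return X, y


def grid_search_train(
    X: pd.DataFrame,
    y: np.ndarray,
    *,
    target_name: str = "target",
    features: Sequence[str] | None = None,
    grid: Mapping[str, Sequence] | None = None,
    cv_seed: int = 0,
    cv_folds: int = 5,
) -> QSARModel:
    """Exhaustive grid search over the SVR hyperparameters.

    The winner is the parameter combination with the best mean K-fold CV
    R^2 (seeded shuffled folds); the final model is refit on all data with
    the winning settings.
    """
    X, y = _check_xy(X, y)
    if len(y) < 20:
        raise QSARError(f"need at least 20 training samples, got {len(y)}")
    feats = list(features) if features is not None else list(X.columns)
    Xf = X[feats].to_numpy(dtype=float)
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=cv_seed)
    best_score, best_params = -np.inf, None
    for params in ParameterGrid(dict(grid or DEFAULT_GRID)):
        model = make_svr()
        model.set_params(**params)
        scores = cross_val_score(model, Xf, y, cv=cv, scoring="r2")
        mean = float(np.mean(scores))
        if mean > best_score:
            best_score, best_params = mean, params
    final = make_svr()
    final.set_params(**best_params)
    final.fit(Xf, y)
    scaler: StandardScaler = final.named_steps["scaler"]
    sds = np.sqrt(scaler.var_)
    if np.any(sds == 0):
        dead = [f for f, s in zip(feats, sds) if s == 0]
        raise QSARError(f"constant features in the training data: {dead}")
    return QSARModel(
        target_name=target_name,
        selected_features=feats,
        scaler_mean={f: float(m) for f, m in zip(feats, scaler.mean_)},
        scaler_sd={f: float(s) for f, s in zip(feats, sds)},
        hyperparameters={k.split("__", 1)[1]: float(v) for k, v in best_params.items()},
        training_ranges={
            f: (float(Xf[:, j].min()), float(Xf[:, j].max())) for j, f in enumerate(feats)
        },
        training_fingerprint=_data_fingerprint(Xf, y),
        estimator=final,
        cv_r2=best_score,
    )


def loo_q2(model_spec, X: pd.DataFrame | np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out Q^2 = 1 - PRESS / SS_tot.

    Each held-out prediction comes from a model trained on the other n-1
    samples; *model_spec* is any sklearn regressor (cloned per fold).
    """
    X_arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    _, y = _check_xy(pd.DataFrame(X_arr), y)
    n = len(y)
    if n < 3:
        raise QSARError("LOO-Q2 needs at least 3 samples")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        m = clone(model_spec)
        m.fit(X_arr[mask], y[mask])
        preds[i] = m.predict(X_arr[i : i + 1])[0]
    press = float(np.sum((y - preds) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss_tot


def _quantile_stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold labels stratified by y-quantile: sort by y, walk consecutive
    blocks of k and deal one sample per fold (seeded within-block shuffle)."""
    n = len(y)
    order = np.argsort(y, kind="mergesort")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    for start in range(0, n, k):
        block = order[start : start + k].copy()
        rng.shuffle(block)
        folds[block] = np.arange(len(block))
    return folds


def kfold_r2(model_spec, X: pd.DataFrame | np.ndarray, y: np.ndarray, k: int, seed: int = 0) -> float:
    """Pooled out-of-fold R^2 over seeded, y-quantile-stratified K folds.

    All out-of-fold predictions are pooled into one vector and a single
    R^2 is computed against the observed values; with k = n this is exactly
    leave-one-out Q^2.
    """
    X_arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    _, y = _check_xy(pd.DataFrame(X_arr), y)
    n = len(y)
    if k > n:
        raise QSARError(f"k = {k} exceeds the number of samples n = {n}")
    if k < 2:
        raise QSARError("need at least 2 folds")
    folds = _quantile_stratified_folds(y, k, seed)
    preds = np.empty(n)
    for fold in range(k):
        test = folds == fold
        m = clone(model_spec)
        m.fit(X_arr[~test], y[~test])
        preds[test] = m.predict(X_arr[test])
    ss_res = float(np.sum((y - preds) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class YRandomizationResult:
    scores: list[float]
    mean: float


def y_randomization(
    model_spec,
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    n_reps: int = 50,
    seed: int = 0,
    k: int = 5,
    permutations: Sequence[np.ndarray] | None = None,
) -> YRandomizationResult:
    """Label-permutation control: permute y, rescore by K-fold CV, repeat.

    An informative model collapses to a score near or below zero once the
    structure-activity link is scrambled; training failures score -inf.
    Explicit *permutations* (index arrays) may be supplied instead of the
    seeded random ones, e.g. the identity permutation as a control.
    """
    if n_reps < 1:
        raise QSARError("n_reps must be >= 1")
    X_arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    _, y = _check_xy(pd.DataFrame(X_arr), y)
    rng = np.random.default_rng(seed)
    scores = []
    for rep in range(n_reps):
        if permutations is not None:
            y_perm = y[np.asarray(permutations[rep], dtype=int)]
        else:
            y_perm = rng.permutation(y)
        try:
            scores.append(kfold_r2(model_spec, X_arr, y_perm, k, seed=seed))
        except Exception:
            scores.append(float("-inf"))
    return YRandomizationResult(scores=scores, mean=float(np.mean(scores)))


def validate_model(
    model: QSARModel,
    X: pd.DataFrame,
    y: np.ndarray,
    *,
    y_rand_reps: int = 50,
    seed: int = 0,
) -> ValidationReport:
    """Compute the full validation panel for a trained model's settings."""
    X, y = _check_xy(X, y)
    Xf = X[model.selected_features]
    spec = make_svr(**model.hyperparameters)
    fitted = model.estimator
    r2_self = float(fitted.score(Xf.to_numpy(dtype=float), y))
    return ValidationReport(
        target_name=model.target_name,
        r2_self=r2_self,
        q2_loo=loo_q2(spec, Xf, y),
        r2_cv5=kfold_r2(spec, Xf, y, 5, seed=seed),
        r2_cv10=kfold_r2(spec, Xf, y, 10, seed=seed),
        y_rand_mean=y_randomization(spec, Xf, y, n_reps=y_rand_reps, seed=seed).mean,
        y_rand_reps=y_rand_reps,
        n_features=len(model.selected_features),
    )


def predict(model: QSARModel, X_new: pd.DataFrame) -> np.ndarray:
    """Apply a fitted model to new descriptor rows (selected features only)."""
    missing = set(model.selected_features) - set(X_new.columns)
    if missing:
        raise QSARError(f"prediction input lacks feature columns: {sorted(missing)}")
    if model.estimator is None:
        raise QSARError("model has no fitted estimator")
    Xf = X_new[model.selected_features].to_numpy(dtype=float)
    return model.estimator.predict(Xf)


def flag_extrapolation(model: QSARModel, X_new: pd.DataFrame) -> np.ndarray:
    """True where any selected feature lies strictly outside its training
    (min, max) range; values exactly on the boundary are inside."""
    missing = set(model.selected_features) - set(X_new.columns)
    if missing:
        raise QSARError(f"input lacks feature columns: {sorted(missing)}")
    Xf = X_new[model.selected_features].to_numpy(dtype=float)
    lows = np.array([model.training_ranges[f][0] for f in model.selected_features])
    highs = np.array([model.training_ranges[f][1] for f in model.selected_features])
    return np.any((Xf < lows) | (Xf > highs), axis=1)


def make_prediction_records(
    models: Mapping[str, QSARModel], X_new: pd.DataFrame, ids: Sequence[str]
) -> list[PredictionRecord]:
    """Joint per-molecule records across all targets, with flags."""
    preds = {t: predict(m, X_new) for t, m in models.items()}
    flags = {t: flag_extrapolation(m, X_new) for t, m in models.items()}
    return [
        PredictionRecord(
            molecule_id=str(mol_id),
            predictions={t: float(preds[t][i]) for t in models},
            extrapolated={t: bool(flags[t][i]) for t in models},
        )
        for i, mol_id in enumerate(ids)
    ]


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise QSARError("vectors have different lengths")
    if len(x) < 3:
        raise QSARError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise QSARError("rank correlation is undefined for a constant vector")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)
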