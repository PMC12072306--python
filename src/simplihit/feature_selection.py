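"""Hybrid descriptor selection: correlation filter, then recursive
elimination, then recursive re-addition.

The three stages compose into a single selector:

1. **CFE** (correlation-based feature elimination) keeps only descriptors
   whose absolute Pearson correlation with activity reaches a threshold
   (default 0.3) — a cheap univariate pre-filter.
2. **RFE** (recursive feature elimination) greedily removes, one per pass,
   the descriptor whose removal most improves the cross-validated model
   score, iterating until no single removal helps.
3. **RFA** (recursive feature addition) revisits everything discarded by
   the first two stages and permanently re-adds any descriptor whose
   addition strictly improves the score — a second chance for descriptors
   with non-linear activity relationships that the univariate filter missed.

Scores are mean R^2 over a seeded 5-fold cross-validation; the folds and
candidate orders are fixed, so the selection is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import KFold, cross_val_score


class SelectionError(ValueError):
    pass


@dataclass
class SelectionConfig:
    """Knobs of the hybrid selector.

    cfe_threshold: minimum |Pearson r| with activity to survive the filter.
    cv_folds / cv_seed: shuffled K-fold used for every model score.
    min_improvement: a step is accepted only if it raises the score by more
        than this (guards float noise).
    rfe_floor: RFE never reduces the working set below this many features.
    """

    cfe_threshold: float = 0.3
    cv_folds: int = 5
    cv_seed: int = 0
    min_improvement: float = 1e-6
    rfe_floor: int = 2


@dataclass
class FeatureSelectionResult:
    selected: list[str]
    removed_by_cfe: list[str]
    removed_by_rfe: list[str]
    readded_by_rfa: list[str]
    score_trace: list[tuple[str, str, float]]  # (action, feature, score after step)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSelectionResult":
        data = json.loads(Path(path).read_text())
        data["score_trace"] = [tuple(t) for t in data["score_trace"]]
        return cls(**data)


ModelFactory = Callable[[], "object"]


def _cv_score(
    model_factory: ModelFactory,
    X: pd.DataFrame,
    y: np.ndarray,
    features: Sequence[str],
    config: SelectionConfig,
) -> float:
    """Mean R^2 over seeded K-fold CV; training failures score -inf."""
    cv = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.cv_seed)
    try:
        scores = cross_val_score(
            clone(model_factory()), X[list(features)].to_numpy(), y, cv=cv, scoring="r2"
        )
        return float(np.mean(scores))
    except Exception:
        return float("-inf")


def cfe(X: pd.DataFrame, y: np.ndarray, threshold: float = 0.3) -> tuple[list[str], list[str]]:
    """Correlation filter: keep features with |Pearson r(feature, y)| >= threshold.

    Undefined correlations (constant feature or zero variance) count as 0.
    Returns (kept, removed), both in the matrix's column order.
    """
    if not 0 < threshold < 1:
        raise SelectionError(f"threshold must be in (0, 1), got {threshold}")
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise SelectionError("X and y have different lengths")
    if len(y) < 3:
        raise SelectionError("need at least 3 samples for a meaningful correlation")
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    kept, removed = [], []
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        xc = x - x.mean()
        sx = np.sqrt((xc**2).sum())
        r = 0.0 if sx == 0 or sy == 0 else float((xc @ yc) / (sx * sy))
        (kept if abs(r) >= threshold else removed).append(name)
    return kept, removed


def rfe(
    features: Sequence[str],
    X: pd.DataFrame,
    y: np.ndarray,
    model_factory: ModelFactory,
    config: SelectionConfig | None = None,
    trace: list | None = None,
) -> tuple[list[str], list[str]]:
    """Greedy backward elimination, iterated to convergence.

    Each pass scores the working set with every single feature left out and
    permanently removes the one whose removal improves the CV score the
    most; ties break towards the earliest column.  Stops when no removal
    improves the score by more than ``min_improvement`` or the floor is hit.
    Returns (surviving, removed) in stable order.
    """
    config = config or SelectionConfig()
    if len(features) < 2:
        raise SelectionError("RFE needs at least 2 features")
    current = list(features)
    removed: list[str] = []
    base = _cv_score(model_factory, X, y, current, config)
    if trace is not None:
        trace.append(("rfe_start", "", base))
    while len(current) > config.rfe_floor:
        best_feature, best_score = None, base
        for f in current:  # column order = tie-break order
            candidate = [g for g in current if g != f]
            s = _cv_score(model_factory, X, y, candidate, config)
            if s > best_score + config.min_improvement:
                best_feature, best_score = f, s
        if best_feature is None:
            break
        current.remove(best_feature)
        removed.append(best_feature)
        base = best_score
        if trace is not None:
            trace.append(("rfe_remove", best_feature, base))
    return current, removed


def rfa(
    candidates: Sequence[str],
    current: Sequence[str],
    X: pd.DataFrame,
    y: np.ndarray,
    model_factory: ModelFactory,
    config: SelectionConfig | None = None,
    trace: list | None = None,
) -> tuple[list[str], list[str]]:
    """Forward re-addition over *candidates* in their given order.

    A candidate is permanently added iff adding it to the working set
    strictly improves the CV score.  Returns (final set, added).
    """
    config = config or SelectionConfig()
    overlap = set(candidates) & set(current)
    if overlap:
        raise SelectionError(f"candidates overlap the current set: {sorted(overlap)}")
    working = list(current)
    added: list[str] = []
    base = _cv_score(model_factory, X, y, working, config)
    for cand in candidates:
        s = _cv_score(model_factory, X, y, working + [cand], config)
        if s > base + config.min_improvement:
            working.append(cand)
            added.append(cand)
            base = s
            if trace is not None:
                trace.append(("rfa_add", cand, base))
    return working, added


def hybrid_select(
    X: pd.DataFrame,
    y: np.ndarray,
    model_factory: ModelFactory,
    config: SelectionConfig | None = None,
) -> FeatureSelectionResult:
    """Full pipeline: CFE, then RFE on the survivors, then RFA over
    everything removed (CFE-removed first, then RFE-removed).

    Deterministic given the config: fixed CV folds and fixed candidate
    orders.  If the correlation filter removes everything, the single
    best-correlated feature pair is retained so downstream stages have a
    working set.
    """
    config = config or SelectionConfig()
    trace: list[tuple[str, str, float]] = []
    kept, removed_cfe = cfe(X, y, config.cfe_threshold)
    if len(kept) < 2:
        # fall back to the top-|r| features so RFE has something to chew on
        y_arr = np.asarray(y, dtype=float)
        corrs = {}
        for name in X.columns:
            x = X[name].to_numpy(dtype=float)
            sx, sy = x.std(), y_arr.std()
            corrs[name] = 0.0 if sx == 0 or sy == 0 else abs(float(np.corrcoef(x, y_arr)[0, 1]))
        top = sorted(X.columns, key=lambda n: (-corrs[n], list(X.columns).index(n)))[:2]
        kept = [n for n in X.columns if n in top]
        removed_cfe = [n for n in X.columns if n not in top]
    if len(kept) >= 2:
        survivors, removed_rfe = rfe(kept, X, y, model_factory, config, trace)
    else:
        survivors, removed_rfe = list(kept), []
    candidates = removed_cfe + removed_rfe  # order of removal, CFE first
    final, readded = rfa(candidates, survivors, X, y, model_factory, config, trace)
    return FeatureSelectionResult(
        selected=final,
        removed_by_cfe=removed_cfe,
        removed_by_rfe=removed_rfe,
        readded_by_rfa=readded,
        score_trace=trace,
    )
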