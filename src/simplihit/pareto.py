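"""Pareto multi-objective ranking of candidates across targets.

All objectives are maximised (predicted pIC50: higher is better).  A point
p dominates q when p >= q in every objective and p > q in at least one; a
candidate's Pareto value is the number of points it dominates, so members
of (or near) the non-dominated front collect the highest values.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from simplihit.simplification import SimplifiedCandidate


class ParetoError(ValueError):
    pass


def _as_points(points) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ParetoError(f"expected a non-empty 2-D objective array, got shape {arr.shape}")
    return arr


def pareto_value(points: Sequence[Sequence[float]]) -> np.ndarray:
    """Dominance count per point: how many other points it dominates.

    Points identical in every objective dominate neither way.  Invariant
    under permutation of the input order.
    """
    arr = _as_points(points)
    n = arr.shape[0]
    # pairwise dominance, vectorised: ge[i, j] = p_i >= p_j everywhere
    ge = np.all(arr[:, None, :] >= arr[None, :, :], axis=2)
    gt = np.any(arr[:, None, :] > arr[None, :, :], axis=2)
    dominates = ge & gt
    np.fill_diagonal(dominates, False)
    return dominates.sum(axis=1).astype(int)


def nondominated_front(points: Sequence[Sequence[float]]) -> list[int]:
    """Indices of points dominated by no other point (the Pareto front)."""
    arr = _as_points(points)
    ge = np.all(arr[:, None, :] >= arr[None, :, :], axis=2)
    gt = np.any(arr[:, None, :] > arr[None, :, :], axis=2)
    dominated_by = (ge & gt).T  # dominated_by[i, j]: j dominates i
    return [i for i in range(arr.shape[0]) if not dominated_by[i].any()]


def round_report(value: float, decimals: int = 2) -> float:
    """Decimal half-even (banker's) rounding used when reporting mean
    pIC50 at two decimal places: ties go to the even digit, so the mean of
    the printed pair (7.81, 7.08) reports as 7.44 and (8.79, 7.23) as 8.01."""
    from decimal import ROUND_HALF_EVEN, Decimal

    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_EVEN))


def rank_candidates(
    candidates: Sequence[SimplifiedCandidate],
    library_means: Iterable[float],
    targets: Sequence[str] | None = None,
) -> list[SimplifiedCandidate]:
    """Attach Pareto values and library ranks; sort best-first.

    ``rank_combinatorial`` is 1 + the number of full-library compounds with
    a strictly greater mean predicted pIC50 — i.e. where each simplified
    candidate would have placed in the original library.  *library_means*
    is consumed as a stream so million-row libraries never need to be in
    memory.  Sorting: Pareto value descending, mean descending, id.
    """
    if not candidates:
        raise ParetoError("no candidates to rank")
    if targets is None:
        targets = sorted(candidates[0].predictions)
    pts = [[c.predictions[t] for t in targets] for c in candidates]
    values = pareto_value(pts)
    means = np.array([c.mean_pic50 for c in candidates])
    greater = np.zeros(len(candidates), dtype=int)
    n_library = 0
    for lib_mean in library_means:
        greater += lib_mean > means
        n_library += 1
    for c, v, g in zip(candidates, values, greater):
        c.pareto_value = int(v)
        c.rank_combinatorial = int(g) + 1 if n_library else -1
    return sorted(
        candidates, key=lambda c: (-c.pareto_value, -c.mean_pic50, c.candidate_id)
    )


def diversity_pick(
    ranked: Sequence[SimplifiedCandidate], quota: int
) -> list[SimplifiedCandidate]:
    """Greedy diversity-aware selection down the ranking.

    Walks the ranked list and keeps a candidate only if it contributes at
    least one (position, substituent) pair not yet represented, so the
    final slate covers as many different substitutions as possible.  Stops
    at *quota* or when the list is exhausted.
    """
    if not ranked:
        raise ParetoError("empty ranking")
    chosen: list[SimplifiedCandidate] = []
    covered: set[tuple[str, str]] = set()
    for cand in ranked:
        if len(chosen) >= quota:
            break
        pairs = set(cand.occupied_positions)
        if pairs - covered:
            chosen.append(cand)
            covered |= pairs
    return chosen
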