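"""Distances between persistence diagrams.

Two metrics, each matched to the homological order it suits:

* q-Wasserstein with partial pairings for H1/H2 — intervals may be matched
  across diagrams (cost: max-norm distance between their endpoint pairs) or
  left unmatched (cost: distance to the diagonal, half the bar length); the
  optimum over pairings is found exactly by a linear assignment on a
  diagonal-augmented cost matrix.
* Hausdorff on death multisets for H0 — every H0 class is born at 0, so the
  diagrams are one-dimensional point clouds of death values and the classic
  Hausdorff max-min distance applies.

`brute_force_wasserstein` enumerates every partial pairing on tiny diagrams
and serves as the independent oracle for the assignment formulation.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .filtration import PersistenceDiagram

__all__ = [
    "interval_gap",
    "interval_distance",
    "wasserstein_distance",
    "brute_force_wasserstein",
    "hausdorff_h0_distance",
    "MetricError",
]


class MetricError(ValueError):
    """Invalid metric input (bad q, essential intervals, empty diagrams)."""


def interval_gap(interval) -> float:
    """Distance of the point (birth, death) to the diagonal: (death - birth)/2."""
    x, y = interval
    return (y - x) / 2.0


def interval_distance(i, j) -> float:
    """Max-norm distance between two intervals as points in the plane."""
    return max(abs(j[0] - i[0]), abs(j[1] - i[1]))


def _as_intervals(dgm, include_zero: bool) -> np.ndarray:
    """Coerce a PersistenceDiagram or (m, 2) array to finite intervals."""
    if isinstance(dgm, PersistenceDiagram):
        if dgm.dim >= 1 and bool(dgm.essential.any()):
            raise MetricError(
                f"H{dgm.dim} diagram contains essential intervals; the "
                "filtration endpoint should have killed them"
            )
        return dgm.persistent(include_zero=include_zero)
    arr = np.asarray(dgm, dtype=float).reshape(-1, 2)
    if not include_zero and len(arr):
        arr = arr[arr[:, 1] > arr[:, 0]]
    return arr


def wasserstein_distance(dgmX, dgmY, q: float = 2.0,
                         include_zero: bool = False) -> float:
    """q-Wasserstein distance between diagrams via optimal partial pairing.

    Minimizes, over partial pairings pi, the sum of matched costs
    d(I, pi(I))^q plus unmatched costs d(I)^q on both sides, then takes the
    q-th root.  Solved exactly as a square assignment problem of size
    (nX + nY): interval i of X may match interval j of Y or its own
    diagonal-projection slot; slot-slot cells cost 0.
    """
    if not q > 1:
        raise MetricError(f"Wasserstein order q must exceed 1, got {q}")
    X = _as_intervals(dgmX, include_zero)
    Y = _as_intervals(dgmY, include_zero)
    nx_, ny_ = len(X), len(Y)
    if nx_ == 0 and ny_ == 0:
        return 0.0
    if nx_ == 0:
        return float(np.sum([interval_gap(j) ** q for j in Y]) ** (1.0 / q))
    if ny_ == 0:
        return float(np.sum([interval_gap(i) ** q for i in X]) ** (1.0 / q))

    big = np.inf
    C = np.zeros((nx_ + ny_, nx_ + ny_))
    # matched block: max-norm cost^q
    dx = np.abs(X[:, 0:1] - Y[:, 0].reshape(1, -1))
    dy = np.abs(X[:, 1:2] - Y[:, 1].reshape(1, -1))
    C[:nx_, :ny_] = np.maximum(dx, dy) ** q
    # diagonal slots
    C[:nx_, ny_:] = big
    C[:nx_, ny_:][np.arange(nx_), np.arange(nx_)] = (
        (X[:, 1] - X[:, 0]) / 2.0) ** q
    C[nx_:, :ny_] = big
    C[nx_:, :ny_][np.arange(ny_), np.arange(ny_)] = (
        (Y[:, 1] - Y[:, 0]) / 2.0) ** q
    # slot-to-slot: free
    C[nx_:, ny_:] = 0.0
    rows, cols = linear_sum_assignment(C)
    return float(C[rows, cols].sum() ** (1.0 / q))


def brute_force_wasserstein(dgmX, dgmY, q: float = 2.0,
                            include_zero: bool = False,
                            guard: int = 8) -> float:
    """Exhaustive minimum over all partial pairings (tiny diagrams only)."""
    if not q > 1:
        raise MetricError(f"Wasserstein order q must exceed 1, got {q}")
    X = _as_intervals(dgmX, include_zero)
    Y = _as_intervals(dgmY, include_zero)
    if len(X) + len(Y) > guard:
        raise MetricError(f"brute-force guard: |X| + |Y| must be <= {guard}")
    gaps_x = [interval_gap(i) ** q for i in X]
    gaps_y = [interval_gap(j) ** q for j in Y]
    best = np.inf
    for size in range(0, min(len(X), len(Y)) + 1):
        for sx in combinations(range(len(X)), size):
            for sy in permutations(range(len(Y)), size):
                cost = sum(interval_distance(X[a], Y[b]) ** q
                           for a, b in zip(sx, sy))
                cost += sum(gaps_x[a] for a in range(len(X)) if a not in sx)
                cost += sum(gaps_y[b] for b in range(len(Y)) if b not in sy)
                best = min(best, cost)
    return float(best ** (1.0 / q))


def hausdorff_h0_distance(dgmX, dgmY, include_zero: bool = False) -> float:
    """Hausdorff distance between H0 death multisets.

    H0 bars all start at 0, so each diagram reduces to its multiset of death
    values on the real line; the essential component's capped death (1.0) is
    included on both sides.  Insensitive to multiplicity by construction.
    """
    def deaths(dgm) -> np.ndarray:
        if isinstance(dgm, PersistenceDiagram):
            if dgm.dim != 0:
                raise MetricError("hausdorff_h0_distance expects H0 diagrams")
            return dgm.death_multiset(include_zero=include_zero)
        return np.asarray(dgm, dtype=float).ravel()

    dx, dy = deaths(dgmX), deaths(dgmY)
    if len(dx) == 0 or len(dy) == 0:
        raise MetricError("Hausdorff distance undefined for empty death sets")
    diff = np.abs(dx[:, None] - dy[None, :])
    return float(max(diff.min(axis=1).max(), diff.min(axis=0).max()))
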