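"""Flag-complex filtrations and persistent homology over GF(2).

The connectome's dissimilarities d = 1 - w induce a Vietoris-Rips-style
filtration of the flag (clique) complex: a simplex enters at the largest
pairwise dissimilarity among its vertices, which is exactly the first
threshold at which its vertices form a clique in the threshold graph.
Persistence is computed by the standard boundary-matrix reduction with the
twist (clearing) optimization; columns are stored as Python big integers,
one bit per simplex, so column additions are single XOR operations.

A brute-force Betti oracle (`brute_force_betti`) computes boundary-operator
ranks directly on small complexes and is used throughout the test suite to
validate the reduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .connectome import DissimilarityMatrix

__all__ = [
    "FilteredComplex",
    "PersistenceDiagram",
    "BettiCurve",
    "FiltrationError",
    "build_flag_filtration",
    "compute_persistence",
    "persistence_from_fc",
    "betti_curve",
    "brute_force_betti",
]

#: highest dimension of simplices enumerated by default (resolves H2 deaths)
DEFAULT_MAX_DIM = 3

#: default vertex-count cap for max_dim = 3 (tetrahedron enumeration is O(n^4))
DEFAULT_N_CAP = 80


class FiltrationError(ValueError):
    """Invalid filtration request or malformed filtration order."""


@dataclass(frozen=True)
class FilteredComplex:
    """Flag complex with simplices in filtration order.

    Simplices are sorted by (filtration value, dimension, lexicographic
    vertex tuple), which guarantees every face precedes its cofaces: a face
    has filtration value <= the coface's (max over a subset of the same
    pairwise dissimilarities) and strictly smaller dimension.
    """

    vertices: tuple[tuple[int, ...], ...]
    values: np.ndarray
    dims: np.ndarray
    max_dim: int
    n: int

    def __len__(self) -> int:
        return len(self.vertices)

    def validate(self) -> None:
        """Check faces-before-cofaces; raise FiltrationError on violation."""
        index = {v: i for i, v in enumerate(self.vertices)}
        for i, simp in enumerate(self.vertices):
            if len(simp) == 1:
                continue
            for face in combinations(simp, len(simp) - 1):
                j = index.get(face)
                if j is None or j >= i:
                    raise FiltrationError(
                        f"face {face} of simplex {simp} missing or out of order"
                    )


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of (birth, death) intervals for one homological dimension.

    Essential classes (never dying inside the filtration) carry
    ``essential=True``; for H0 the single surviving component's death is
    capped at 1.0, the endpoint of the dissimilarity domain.  Zero-length
    intervals (birth == death) are retained for bookkeeping but excluded
    from diagram distances by default.
    """

    dim: int
    births: np.ndarray
    deaths: np.ndarray
    essential: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.births, dtype=float)
        d = np.asarray(self.deaths, dtype=float)
        e = np.asarray(self.essential, dtype=bool)
        if not (b.shape == d.shape == e.shape):
            raise FiltrationError("births, deaths, essential must share shape")
        if np.any(d < b - 1e-12):
            raise FiltrationError("interval death precedes birth")
        for arr in (b, d, e):
            arr.setflags(write=False)
        object.__setattr__(self, "births", b)
        object.__setattr__(self, "deaths", d)
        object.__setattr__(self, "essential", e)

    def __len__(self) -> int:
        return len(self.births)

    def persistent(self, include_zero: bool = False) -> np.ndarray:
        """Finite (non-essential) intervals as an (m, 2) array."""
        keep = ~self.essential
        if not include_zero:
            keep &= self.deaths > self.births
        return np.column_stack([self.births[keep], self.deaths[keep]])

    def death_multiset(self, include_zero: bool = False,
                       include_essential: bool = True) -> np.ndarray:
        """Death values (H0 barcode endpoints), essentials capped at 1.0."""
        keep = np.ones(len(self), dtype=bool)
        if not include_zero:
            keep &= (self.deaths > self.births) | self.essential
        if not include_essential:
            keep &= ~self.essential
        return self.deaths[keep]

    def betti_at(self, t: float) -> int:
        """Number of classes alive at threshold t (birth <= t < death)."""
        alive = (self.births <= t) & ((t < self.deaths) | self.essential)
        return int(alive.sum())


@dataclass(frozen=True)
class BettiCurve:
    """Betti numbers per dimension along a shared threshold grid."""

    thresholds: np.ndarray
    betti: dict[int, np.ndarray]


def build_flag_filtration(D: DissimilarityMatrix | np.ndarray,
                          max_dim: int = DEFAULT_MAX_DIM,
                          n_cap: int = DEFAULT_N_CAP) -> FilteredComplex:
    """Enumerate all cliques of size <= max_dim + 1 with VR filtration values.

    To measure H_p the complex must contain simplices up to dimension p + 1,
    so ``max_dim`` = 2 suffices for H0/H1 and ``max_dim`` = 3 for H2.
    """
    if max_dim not in (1, 2, 3):
        raise FiltrationError(f"max_dim must be 1, 2 or 3, got {max_dim}")
    Dm = D.D if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)
    n = Dm.shape[0]
    if max_dim == 3 and n > n_cap:
        raise FiltrationError(
            f"n={n} exceeds cap {n_cap} for max_dim=3; raise n_cap explicitly "
            "or lower max_dim"
        )

    simplices: list[tuple[int, ...]] = [(v,) for v in range(n)]
    values: list[np.ndarray] = [np.zeros(n)]
    dims: list[np.ndarray] = [np.zeros(n, dtype=np.int8)]

    combos = list(combinations(range(n), 2))
    idx = np.array(combos)
    vals = Dm[idx[:, 0], idx[:, 1]]
    simplices.extend(combos)
    values.append(vals)
    dims.append(np.ones(len(combos), dtype=np.int8))

    if max_dim >= 2 and n >= 3:
        combos = list(combinations(range(n), 3))
        idx = np.array(combos)
        vals = np.maximum.reduce([
            Dm[idx[:, a], idx[:, b]] for a, b in combinations(range(3), 2)
        ])
        simplices.extend(combos)
        values.append(vals)
        dims.append(np.full(len(combos), 2, dtype=np.int8))

    if max_dim >= 3 and n >= 4:
        combos = list(combinations(range(n), 4))
        idx = np.array(combos)
        vals = np.maximum.reduce([
            Dm[idx[:, a], idx[:, b]] for a, b in combinations(range(4), 2)
        ])
        simplices.extend(combos)
        values.append(vals)
        dims.append(np.full(len(combos), 3, dtype=np.int8))

    all_vals = np.concatenate(values)
    all_dims = np.concatenate(dims)
    order = sorted(range(len(simplices)),
                   key=lambda i: (all_vals[i], int(all_dims[i]), simplices[i]))
    verts = tuple(simplices[i] for i in order)
    return FilteredComplex(
        vertices=verts,
        values=all_vals[order],
        dims=all_dims[order],
        max_dim=max_dim,
        n=n,
    )


def _reduce(fc_complex: FilteredComplex) -> tuple[dict[int, int], set[int]]:
    """Twist-optimized GF(2) column reduction.

    Returns (pairs, cleared): ``pairs`` maps birth-simplex index to
    death-simplex index; ``cleared`` is the set of paired birth simplices
    whose own columns were skipped.
    """
    verts = fc_complex.vertices
    dims = fc_complex.dims
    index = {v: i for i, v in enumerate(verts)}
    m = len(verts)

    by_dim: dict[int, list[int]] = {}
    for i in range(m):
        by_dim.setdefault(int(dims[i]), []).append(i)

    pairs: dict[int, int] = {}
    cleared: set[int] = set()
    for p in range(fc_complex.max_dim, 0, -1):
        pivot: dict[int, int] = {}  # row (face index) -> reduced column bitmask
        for c in by_dim.get(p, []):
            if c in cleared:
                continue
            simp = verts[c]
            col = 0
            for face in combinations(simp, p):
                col |= 1 << index[face]
            while col:
                r = col.bit_length() - 1
                other = pivot.get(r)
                if other is None:
                    break
                col ^= other
            if col:
                r = col.bit_length() - 1
                pivot[r] = col
                pairs[r] = c
                cleared.add(r)
    return pairs, cleared


def compute_persistence(fc_complex: FilteredComplex,
                        validate: bool = False) -> list[PersistenceDiagram]:
    """Persistence diagrams for p = 0 .. max_dim - 1.

    Under the dissimilarity convention d = 1 - w with w >= 0, the complex at
    filtration value 1 contains every simplex, so H1/H2 classes all die
    within the filtration and the only essential class is one H0 component,
    whose death is capped at 1.0.
    """
    if validate:
        fc_complex.validate()
    pairs, cleared = _reduce(fc_complex)
    values = fc_complex.values
    dims = fc_complex.dims
    m = len(fc_complex)

    out: list[PersistenceDiagram] = []
    births: dict[int, list[float]] = {p: [] for p in range(fc_complex.max_dim)}
    deaths: dict[int, list[float]] = {p: [] for p in range(fc_complex.max_dim)}
    ess: dict[int, list[bool]] = {p: [] for p in range(fc_complex.max_dim)}

    negative = set(pairs.values())
    for r, c in pairs.items():
        p = int(dims[r])
        births[p].append(float(values[r]))
        deaths[p].append(float(values[c]))
        ess[p].append(False)
    for i in range(m):
        p = int(dims[i])
        if p >= fc_complex.max_dim or i in cleared or i in negative:
            continue
        # positive simplex never paired by a coface: essential class
        births[p].append(float(values[i]))
        deaths[p].append(1.0 if p == 0 else float("inf"))
        ess[p].append(True)

    for p in range(fc_complex.max_dim):
        order = np.lexsort((deaths[p], births[p])) if births[p] else []
        out.append(PersistenceDiagram(
            dim=p,
            births=np.asarray(births[p], dtype=float)[order],
            deaths=np.asarray(deaths[p], dtype=float)[order],
            essential=np.asarray(ess[p], dtype=bool)[order],
        ))
    return out


def persistence_from_fc(fc, max_dim: int = DEFAULT_MAX_DIM,
                        n_cap: int = DEFAULT_N_CAP) -> list[PersistenceDiagram]:
    """Convenience: FCMatrix -> dissimilarity -> flag filtration -> diagrams."""
    from .connectome import dissimilarity_matrix

    return compute_persistence(
        build_flag_filtration(dissimilarity_matrix(fc), max_dim=max_dim, n_cap=n_cap)
    )


def betti_curve(dgms: Sequence[PersistenceDiagram],
                thresholds: Iterable[float]) -> BettiCurve:
    """Betti numbers at each threshold: classes with birth <= t < death,
    plus essentials with birth <= t."""
    ts = np.asarray(sorted(thresholds), dtype=float)
    betti = {d.dim: np.array([d.betti_at(t) for t in ts], dtype=int) for d in dgms}
    return BettiCurve(thresholds=ts, betti=betti)


def _gf2_rank(cols: list[int]) -> int:
    rank = 0
    pivots: dict[int, int] = {}
    for col in cols:
        while col:
            r = col.bit_length() - 1
            other = pivots.get(r)
            if other is None:
                pivots[r] = col
                rank += 1
                break
            col ^= other
    return rank


def brute_force_betti(D: DissimilarityMatrix | np.ndarray, t: float, p: int,
                      n_guard: int = 14) -> int:
    """b_p of the flag complex at threshold t by direct boundary ranks.

    Independent of the persistence machinery: enumerates the sub-complex
    with filtration value <= t and returns
    dim C_p - rank(boundary_p) - rank(boundary_{p+1}) over GF(2).
    Guarded to small n (combinatorial enumeration up to (p+1)-simplices).
    """
    Dm = D.D if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)
    n = Dm.shape[0]
    if n > n_guard:
        raise FiltrationError(f"brute-force oracle limited to n <= {n_guard}")
    if p not in (0, 1, 2):
        raise FiltrationError("p must be 0, 1 or 2")

    def cliques(size: int) -> list[tuple[int, ...]]:
        out = []
        for c in combinations(range(n), size):
            if all(Dm[a, b] <= t for a, b in combinations(c, 2)):
                out.append(c)
        return out

    p_simp = cliques(p + 1)
    if not p_simp:
        return 0
    if p == 0:
        rank_dp = 0
    else:
        faces = {f: i for i, f in enumerate(cliques(p))}
        cols = []
        for s in p_simp:
            col = 0
            for f in combinations(s, p):
                col |= 1 << faces[f]
            cols.append(col)
        rank_dp = _gf2_rank(cols)
    cofaces = cliques(p + 2)
    faces = {f: i for i, f in enumerate(p_simp)}
    cols = []
    for s in cofaces:
        col = 0
        for f in combinations(s, p + 1):
            col |= 1 << faces[f]
        cols.append(col)
    rank_dp1 = _gf2_rank(cols)
    return len(p_simp) - rank_dp - rank_dp1
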