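"""Functional connectomes as weighted graphs.

A functional connectome (FC) is the complete weighted graph on a set of
brain regions whose edge weights are absolute Pearson correlations between
regional time series, so every weight lies in [0, 1] and the diagonal is 1.
This module builds FCs from time series, averages them across subjects,
partitions them into functional networks (FNs), thresholds them into graph
filtrations, and contracts them into FN-level super-graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "FCMatrix",
    "DissimilarityMatrix",
    "Partition",
    "ThresholdGraph",
    "SuperGraph",
    "ConnectomeError",
    "fc_from_timeseries",
    "group_average_fc",
    "dissimilarity_matrix",
    "weight_levels",
    "threshold_graph",
    "graph_betti",
    "induced_subnetwork",
    "consolidate_supergraph",
]

_SYMMETRY_TOL = 1e-8


class ConnectomeError(ValueError):
    """Invalid connectome, partition, or threshold input."""


def _default_ids(n: int) -> tuple[str, ...]:
    return tuple(f"R{i}" for i in range(n))


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric matrix of functional couplings w_uv in [0, 1], diagonal 1."""

    W: np.ndarray
    region_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ConnectomeError(f"FC matrix must be square, got shape {W.shape}")
        if not np.allclose(W, W.T, atol=_SYMMETRY_TOL):
            raise ConnectomeError("FC matrix is not symmetric (tolerance 1e-8)")
        W = (W + W.T) / 2.0
        if W.min() < 0.0 or W.max() > 1.0 + 1e-12:
            raise ConnectomeError("FC weights must lie in [0, 1]")
        np.fill_diagonal(W, 1.0)
        W.setflags(write=False)
        object.__setattr__(self, "W", W)
        ids = tuple(self.region_ids) if self.region_ids else _default_ids(W.shape[0])
        if len(ids) != W.shape[0]:
            raise ConnectomeError("region_ids length does not match matrix size")
        if len(set(ids)) != len(ids):
            raise ConnectomeError("region_ids must be unique")
        object.__setattr__(self, "region_ids", ids)

    @property
    def n(self) -> int:
        return self.W.shape[0]


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Pairwise dissimilarities d_uv = 1 - w_uv; diagonal 0."""

    D: np.ndarray
    region_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ConnectomeError(f"dissimilarity matrix must be square, got {D.shape}")
        if not np.allclose(D, D.T, atol=_SYMMETRY_TOL):
            raise ConnectomeError("dissimilarity matrix is not symmetric")
        D = (D + D.T) / 2.0
        if D.min() < -1e-12 or D.max() > 1.0 + 1e-12:
            raise ConnectomeError("dissimilarities must lie in [0, 1]")
        np.fill_diagonal(D, 0.0)
        D = np.clip(D, 0.0, 1.0)
        D.setflags(write=False)
        object.__setattr__(self, "D", D)
        ids = tuple(self.region_ids) if self.region_ids else _default_ids(D.shape[0])
        if len(ids) != D.shape[0]:
            raise ConnectomeError("region_ids length does not match matrix size")
        object.__setattr__(self, "region_ids", ids)

    @property
    def n(self) -> int:
        return self.D.shape[0]


@dataclass(frozen=True)
class Partition:
    """Membership vector sigma assigning each region to one of k FN classes.

    ``sigma[u]`` is the index into ``class_names`` of region u's functional
    network.  Every class must be non-empty (a disjoint vertex covering).
    """

    sigma: np.ndarray
    class_names: tuple[str, ...]
    region_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        sigma = np.asarray(self.sigma, dtype=int)
        sigma.setflags(write=False)
        object.__setattr__(self, "sigma", sigma)
        names = tuple(self.class_names)
        object.__setattr__(self, "class_names", names)
        if sigma.ndim != 1:
            raise ConnectomeError("sigma must be a vector")
        if len(set(names)) != len(names):
            raise ConnectomeError("class names must be unique")
        if sigma.min(initial=0) < 0 or sigma.max(initial=-1) >= len(names):
            raise ConnectomeError("sigma labels out of range of class_names")
        present = set(sigma.tolist())
        missing = [names[i] for i in range(len(names)) if i not in present]
        if missing:
            raise ConnectomeError(f"empty partition classes: {missing}")
        ids = tuple(self.region_ids) if self.region_ids else _default_ids(len(sigma))
        if len(ids) != len(sigma):
            raise ConnectomeError("region_ids length does not match sigma")
        object.__setattr__(self, "region_ids", ids)

    @property
    def k(self) -> int:
        return len(self.class_names)

    @property
    def n(self) -> int:
        return len(self.sigma)

    def members(self, class_id: str) -> np.ndarray:
        """Indices of the regions belonging to ``class_id``, in region order."""
        if class_id not in self.class_names:
            raise ConnectomeError(f"unknown partition class {class_id!r}")
        return np.flatnonzero(self.sigma == self.class_names.index(class_id))


@dataclass(frozen=True)
class ThresholdGraph:
    """Binary graph at cut-off r: edge {u, v} present iff w_uv >= r, u != v."""

    graph: nx.Graph
    r: float
    region_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class SuperGraph:
    """FN-level quotient graph: summed cross-class weights, max-normalized."""

    raw: np.ndarray
    normalized: FCMatrix
    class_names: tuple[str, ...] = field(default=())


def fc_from_timeseries(values: np.ndarray, region_ids: Sequence[str] | None = None) -> FCMatrix:
    """Absolute Pearson correlation matrix of region x time signals.

    Rows are regions, columns are time points.  Constant rows are rejected
    (their correlation is undefined).  The diagonal is forced to exactly 1.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ConnectomeError("time series must be a 2-D regions x timepoints array")
    if X.shape[1] < 2:
        raise ConnectomeError("need at least 2 timepoints per region")
    ids = tuple(region_ids) if region_ids is not None else _default_ids(X.shape[0])
    sd = X.std(axis=1)
    flat = np.flatnonzero(sd == 0.0)
    if flat.size:
        raise ConnectomeError(
            f"constant time series for region(s) {[ids[i] for i in flat]}: "
            "Pearson correlation undefined"
        )
    W = np.abs(np.corrcoef(X))
    W = np.clip(W, 0.0, 1.0)  # guard fp overshoot beyond |r| = 1
    np.fill_diagonal(W, 1.0)
    return FCMatrix(W, ids)


def group_average_fc(fcs: Sequence[FCMatrix]) -> FCMatrix:
    """Entrywise mean of subject-level FCs sharing a region order."""
    if not fcs:
        raise ConnectomeError("cannot average an empty list of FC matrices")
    ids = fcs[0].region_ids
    for fc in fcs[1:]:
        if fc.region_ids != ids:
            raise ConnectomeError("FC matrices have mismatched region_ids")
    W = np.mean([fc.W for fc in fcs], axis=0)
    np.fill_diagonal(W, 1.0)
    return FCMatrix(W, ids)


def dissimilarity_matrix(fc: FCMatrix) -> DissimilarityMatrix:
    """d_uv = 1 - w_uv."""
    return DissimilarityMatrix(1.0 - fc.W, fc.region_ids)


def weight_levels(fc: FCMatrix) -> list[float]:
    """Unique off-diagonal weights, strictly decreasing.

    Exact floating-point equality defines uniqueness; callers wanting coarser
    levels should round the matrix first.
    """
    n = fc.n
    iu = np.triu_indices(n, k=1)
    vals = np.unique(fc.W[iu])
    return list(vals[::-1])


def threshold_graph(fc: FCMatrix, r: float) -> ThresholdGraph:
    """Graph with an edge wherever w_uv >= r (ties included)."""
    if not 0.0 <= r <= 1.0:
        raise ConnectomeError(f"threshold r={r} outside [0, 1]")
    g = nx.Graph()
    g.add_nodes_from(range(fc.n))
    iu, ju = np.triu_indices(fc.n, k=1)
    keep = fc.W[iu, ju] >= r
    g.add_edges_from(zip(iu[keep].tolist(), ju[keep].tolist()))
    return ThresholdGraph(g, float(r), fc.region_ids)


def graph_betti(tg: ThresholdGraph) -> tuple[int, int]:
    """Graph-level Betti numbers (b0, b1).

    b0 counts connected components; b1 = |E| - |V| + b0 counts independent
    graph cycles.  Note b1 of the graph and b1 of its clique complex differ
    once triangles exist: the graph count only ever grows along a filtration
    while the simplicial count can fall as triangles fill cycles in.
    """
    g = tg.graph
    b0 = nx.number_connected_components(g)
    b1 = g.number_of_edges() - g.number_of_nodes() + b0
    return b0, b1


def induced_subnetwork(fc: FCMatrix, part: Partition, class_id: str) -> FCMatrix:
    """Principal submatrix of W on one FN's regions, region order preserved."""
    if part.n != fc.n:
        raise ConnectomeError("partition does not cover this connectome")
    idx = part.members(class_id)
    sub = fc.W[np.ix_(idx, idx)].copy()
    ids = tuple(fc.region_ids[i] for i in idx)
    return FCMatrix(sub, ids)


def consolidate_supergraph(fc: FCMatrix, part: Partition) -> SuperGraph:
    """Quotient the connectome by its FN partition.

    Cross-class weights are summed, W_ij = sum over u in class i, v in class j
    of w_uv, then max-normalized over off-diagonal entries so the strongest
    FN-FN coupling is exactly 1.  The diagonal of the normalized matrix is set
    to 1 so the result is itself a valid FC and all homology operations apply
    to it unchanged.
    """
    if part.n != fc.n:
        raise ConnectomeError("partition does not cover this connectome")
    k = part.k
    raw = np.zeros((k, k))
    members = [part.members(c) for c in part.class_names]
    for i in range(k):
        for j in range(i + 1, k):
            raw[i, j] = raw[j, i] = fc.W[np.ix_(members[i], members[j])].sum()
    mx = raw.max()
    if mx > 0:
        norm = raw / mx
    else:
        warnings.warn("all cross-class weights are zero; normalized super-graph is zero")
        norm = raw.copy()
    np.fill_diagonal(norm, 1.0)
    return SuperGraph(raw=raw, normalized=FCMatrix(norm, part.class_names),
                      class_names=part.class_names)
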