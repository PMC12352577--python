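"""Multi-level rest/task landscape analyses.

Given persistence diagrams per condition (and per functional network),
this module assembles the study's analysis levels: pairwise diagram-distance
tables with per-condition mean/variance profiles and the most distinct
pair; subject-level consensus voting on the most distinct pair; per-subject
all-to-REST distance vectors; histogram-based KL divergence between the
all-to-REST distributions of two functional networks; and top-k ranking of
FN pairs by KL divergence.

The metric is bound to the homological order as in the underlying study —
Hausdorff on death values for H0, q-Wasserstein for H1/H2 — but every
function accepts an explicit override.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .filtration import PersistenceDiagram
from .metrics import hausdorff_h0_distance, wasserstein_distance

__all__ = [
    "ConditionSet",
    "DistanceTable",
    "ConsensusCount",
    "LandscapeError",
    "diagram_distance",
    "pairwise_distance_table",
    "most_distinct_pair",
    "condition_profiles",
    "consensus_vote",
    "all_to_rest_distances",
    "kl_divergence",
    "top_k_fn_pairs",
]

REST = "REST"


class LandscapeError(ValueError):
    """Missing diagrams, mismatched labels, or invalid analysis request."""


def _default_metric(dim: int) -> str:
    return "hausdorff_h0" if dim == 0 else "wasserstein"


def diagram_distance(a: PersistenceDiagram, b: PersistenceDiagram,
                     dim: int, metric: str | None = None,
                     q: float = 2.0) -> float:
    """Dispatch to the metric bound to a homological dimension."""
    metric = metric or _default_metric(dim)
    if metric == "hausdorff_h0":
        return hausdorff_h0_distance(a, b)
    if metric == "wasserstein":
        return wasserstein_distance(a, b, q=q)
    raise LandscapeError(f"unknown metric {metric!r}")


@dataclass(frozen=True)
class ConditionSet:
    """Diagrams per (condition label, homological dimension)."""

    labels: tuple[str, ...]
    diagrams: Mapping[tuple[str, int], PersistenceDiagram]

    def get(self, label: str, dim: int) -> PersistenceDiagram:
        try:
            return self.diagrams[(label, dim)]
        except KeyError:
            raise LandscapeError(f"no diagram for ({label!r}, H{dim})") from None


@dataclass(frozen=True)
class DistanceTable:
    """Symmetric condition-by-condition (or FN-by-FN) diagram distances."""

    labels: tuple[str, ...]
    M: np.ndarray
    metric: str
    dim: int
    q: float = 2.0

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        if M.shape != (len(self.labels),) * 2:
            raise LandscapeError("distance matrix shape does not match labels")
        if not np.allclose(M, M.T):
            raise LandscapeError("distance matrix must be symmetric")
        if np.any(np.diag(M) != 0) or M.min() < 0:
            raise LandscapeError("distances must be non-negative with zero diagonal")
        M.setflags(write=False)
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "labels", tuple(self.labels))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.M, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class ConsensusCount:
    """Votes per unordered label pair: how many subjects had it most distinct."""

    labels: tuple[str, ...]
    C: np.ndarray  # upper-triangular counts
    n_subjects: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.C, index=self.labels, columns=self.labels)

    def modal_pair(self) -> tuple[str, str]:
        """The most-voted pair; ties broken lexicographically by label names."""
        best, best_votes = None, -1
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                pair = tuple(sorted((self.labels[i], self.labels[j])))
                votes = int(self.C[i, j])
                if votes > best_votes or (votes == best_votes and pair < best):
                    best, best_votes = pair, votes
        return best


def pairwise_distance_table(cset: ConditionSet, dim: int,
                            metric: str | None = None,
                            q: float = 2.0) -> DistanceTable:
    """All pairwise diagram distances among the set's conditions at one dim."""
    metric = metric or _default_metric(dim)
    k = len(cset.labels)
    M = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            M[i, j] = M[j, i] = diagram_distance(
                cset.get(cset.labels[i], dim), cset.get(cset.labels[j], dim),
                dim=dim, metric=metric, q=q)
    return DistanceTable(tuple(cset.labels), M, metric, dim, q)


def most_distinct_pair(tbl: DistanceTable) -> tuple[str, str]:
    """Unordered pair with the largest distance, lexicographic tie-break."""
    best, best_val = None, -np.inf
    for i in range(len(tbl.labels)):
        for j in range(i + 1, len(tbl.labels)):
            pair = tuple(sorted((tbl.labels[i], tbl.labels[j])))
            v = tbl.M[i, j]
            if v > best_val or (v == best_val and pair < best):
                best, best_val = pair, v
    if best is None:
        raise LandscapeError("need at least two labels")
    return best


def condition_profiles(tbl: DistanceTable) -> tuple[pd.Series, pd.Series, tuple[str, str]]:
    """Per-condition mean and population variance of its distances to the
    other conditions, plus the most distinct pair."""
    if len(tbl.labels) < 2:
        raise LandscapeError("need at least two labels for profiles")
    off = tbl.M.copy()
    n = len(tbl.labels)
    mask = ~np.eye(n, dtype=bool)
    rows = [off[i][mask[i]] for i in range(n)]
    means = pd.Series([r.mean() for r in rows], index=tbl.labels, name="mean")
    variances = pd.Series([r.var() for r in rows], index=tbl.labels, name="variance")
    return means, variances, most_distinct_pair(tbl)


def consensus_vote(tables: Sequence[DistanceTable]) -> ConsensusCount:
    """Count, per unordered pair, the subjects for which it is most distinct."""
    if not tables:
        raise LandscapeError("no subject tables to vote over")
    labels = tables[0].labels
    for t in tables[1:]:
        if t.labels != labels:
            raise LandscapeError("subject tables have mismatched labels")
    k = len(labels)
    C = np.zeros((k, k), dtype=int)
    pos = {lab: i for i, lab in enumerate(labels)}
    for t in tables:
        a, b = most_distinct_pair(t)
        i, j = sorted((pos[a], pos[b]))
        C[i, j] += 1
    return ConsensusCount(labels, C, n_subjects=len(tables))


def all_to_rest_distances(
    subject_diagrams: Mapping[str, Mapping[tuple[str, str], Mapping[int, PersistenceDiagram]]],
    fn: str, task: str, dim: int,
    metric: str | None = None, q: float = 2.0,
    rest_label: str = REST,
) -> np.ndarray:
    """Per-subject distance between (fn, task) and (fn, REST) diagrams.

    ``subject_diagrams`` maps subject -> (fn, condition) -> dim -> diagram;
    the returned vector follows sorted subject order.
    """
    out = []
    for subject in sorted(subject_diagrams):
        per = subject_diagrams[subject]
        try:
            a = per[(fn, task)][dim]
            b = per[(fn, rest_label)][dim]
        except KeyError as exc:
            raise LandscapeError(
                f"subject {subject!r} missing diagram for FN {fn!r}, "
                f"condition {exc.args[0]!r}"
            ) from None
        out.append(diagram_distance(a, b, dim=dim, metric=metric, q=q))
    return np.asarray(out)


def kl_divergence(p_samples, q_samples, bins: int = 10,
                  pseudocount: float = 1.0) -> float:
    """KL(P || Q) between two samples via shared-grid histograms.

    Both samples are histogrammed on ``bins`` equal-width bins spanning the
    pooled range; ``pseudocount`` is added to every bin before normalizing
    so the divergence is finite on disjoint supports.  Natural logarithm.
    A degenerate pooled range (all values identical) yields 0.
    """
    p = np.asarray(p_samples, dtype=float).ravel()
    qs = np.asarray(q_samples, dtype=float).ravel()
    if len(p) == 0 or len(qs) == 0:
        raise LandscapeError("KL divergence needs non-empty samples")
    lo = min(p.min(), qs.min())
    hi = max(p.max(), qs.max())
    if hi == lo:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    hp, _ = np.histogram(p, bins=edges)
    hq, _ = np.histogram(qs, bins=edges)
    hp = hp + pseudocount
    hq = hq + pseudocount
    hp = hp / hp.sum()
    hq = hq / hq.sum()
    return float(np.sum(hp * np.log(hp / hq)))


def top_k_fn_pairs(kl_table: Mapping[tuple[str, str], float],
                   k: int) -> list[tuple[tuple[str, str], float, float]]:
    """k largest entries, descending, with strengths normalized to the top.

    Ties are broken lexicographically by pair.  Each item is
    (pair, value, value / max-of-selected); when the selected maximum is 0
    all strengths are reported as 1 (uniform, nothing to scale by).
    """
    if k <= 0:
        raise LandscapeError("k must be positive")
    if k > len(kl_table):
        raise LandscapeError(f"k={k} exceeds number of FN pairs ({len(kl_table)})")
    items = sorted(kl_table.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    top = items[0][1]
    return [(pair, val, val / top if top > 0 else 1.0) for pair, val in items]
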