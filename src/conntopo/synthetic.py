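"""Synthetic modular-connectome cohorts with planted rest/task effects.

Emulates, at desk scale, the structure of a multi-condition fMRI cohort:
subjects x conditions (one resting condition plus several tasks), regions
grouped into functional networks (FNs) with stronger within- than
between-network coupling, and condition-specific coupling perturbations.

Regional signals follow a linear latent-factor model with a
circular-harmonic within-FN component.  The m regions of FN i sit at ring
positions theta_u = 2*pi*u/m — emulating spatially organized within-network
gradients (somatotopic and retinotopic maps are the canonical examples) —
and region u's signal under one condition is

    x_u(t) = lam * [sqrt(1 - rho) * c_i(t)
                    + sqrt(rho) * (cos(theta_u) a_i(t) + sin(theta_u) b_i(t))]
             + beta * g(t) + sqrt(1 - lam^2 - beta^2) * eps_u(t)

with a_i, b_i, c_i the FN factors, g a global factor, eps_u unit noise (all
iid standard normal), lam the subject- and condition-specific loading of FN
i, beta the global loading and rho the ring share of the FN factor
variance.  Signals have unit variance, so population correlations have
closed forms used by the tests:

    corr(u, v) = lam_u lam_v [(1 - rho) + rho cos(theta_u - theta_v)] + beta^2
    corr(u, v) = beta^2                       (u, v in different FNs)

The ring makes each FN carry one genuinely persistent H1 loop (neighbours
correlate strongly, antipodes only through the shared component), and the
loop's persistence scales with the FN's loading — so a task effect on one
FN's coupling is visible to first-homology analyses, not only to
connectivity averages.  Task effects add delta to the loading of designated
(condition, FN) pairs; subject heterogeneity jitters each subject's FN
loadings once, shared across that subject's conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .connectome import ConnectomeError, FCMatrix, Partition, fc_from_timeseries

__all__ = [
    "CohortSpec",
    "PlantedTruth",
    "make_partition",
    "simulate_cohort",
    "default_cohort_spec",
]

REST = "REST"

#: desk-scale defaults: 5 FNs over 40 regions
DEFAULT_CLASS_SIZES = (10, 10, 8, 6, 6)
DEFAULT_CLASS_NAMES = ("VIS", "SM", "DA", "LIM", "DMN")

#: every task loads on SM with a different strength; MOT loads hardest, so
#: (MOT, REST) is the planted most-distinct condition pair
DEFAULT_TASK_EFFECTS: Mapping[str, Mapping[str, float]] = {
    "EMOT": {"SM": 0.06},
    "WM": {"SM": 0.10},
    "MOT": {"SM": 0.22},
}


def make_partition(n_regions: int, class_sizes: Sequence[int],
                   class_names: Sequence[str] | None = None,
                   region_ids: Sequence[str] | None = None) -> Partition:
    """Contiguous-block FN partition with the given class sizes."""
    sizes = list(class_sizes)
    if any(s < 1 for s in sizes):
        raise ConnectomeError("every partition class needs at least one region")
    if sum(sizes) != n_regions:
        raise ConnectomeError(
            f"class sizes sum to {sum(sizes)}, expected n_regions={n_regions}")
    names = tuple(class_names) if class_names is not None else tuple(
        f"FN{i + 1}" for i in range(len(sizes)))
    if len(names) != len(sizes):
        raise ConnectomeError("class_names length must match class_sizes")
    sigma = np.repeat(np.arange(len(sizes)), sizes)
    ids = tuple(region_ids) if region_ids is not None else ()
    return Partition(sigma, names, ids)


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition description for a simulated cohort.

    ``within_coupling`` maps FN name to its baseline factor loading
    lam in (0, 1); ``between_coupling`` is the global loading beta; both are
    amplitudes, so the implied correlations are lam^2 + beta^2 (within) and
    beta^2 (between).  ``task_effects`` maps condition -> FN -> additive
    loading perturbation delta; REST must carry no perturbation.  ``seed``
    is required — there is no silent default stream.
    """

    seed: int
    n_subjects: int = 20
    n_regions: int = 40
    class_sizes: tuple[int, ...] = DEFAULT_CLASS_SIZES
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    n_timepoints: int = 300
    conditions: tuple[str, ...] = (REST, "EMOT", "WM", "MOT")
    within_coupling: Mapping[str, float] = field(
        default_factory=lambda: {name: 0.7 for name in DEFAULT_CLASS_NAMES})
    between_coupling: float = 0.2
    ring_share: float = 0.5
    task_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_TASK_EFFECTS.items()})
    subject_sd: float = 0.02

    def partition(self) -> Partition:
        ids = tuple(f"R{i:03d}" for i in range(self.n_regions))
        return make_partition(self.n_regions, self.class_sizes, self.class_names, ids)

    def validate(self) -> None:
        if REST not in self.conditions:
            raise ConnectomeError("conditions must include REST")
        if REST in self.task_effects and any(self.task_effects[REST].values()):
            raise ConnectomeError("REST must have zero perturbation")
        for cond in self.task_effects:
            if cond not in self.conditions:
                raise ConnectomeError(f"task effect for unknown condition {cond!r}")
            for fn in self.task_effects[cond]:
                if fn not in self.class_names:
                    raise ConnectomeError(f"task effect for unknown FN {fn!r}")
        if not 0.0 <= self.ring_share <= 1.0:
            raise ConnectomeError(f"ring_share={self.ring_share} outside [0, 1]")
        beta = self.between_coupling
        for fn in self.class_names:
            lam = self.within_coupling[fn]
            if not 0 < lam < 1:
                raise ConnectomeError(f"within_coupling[{fn!r}]={lam} outside (0, 1)")
            for cond in self.conditions:
                pert = lam + self.task_effects.get(cond, {}).get(fn, 0.0)
                if not 0 < pert < 1 or pert ** 2 + beta ** 2 >= 1:
                    raise ConnectomeError(
                        f"loading for (condition={cond!r}, FN={fn!r}) out of "
                        f"range after perturbation: lam={pert}, beta={beta}")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of the simulated design, for recovery tests."""

    most_perturbed_condition: str
    most_perturbed_fn: str
    effects: Mapping[str, Mapping[str, float]]


def default_cohort_spec(seed: int) -> CohortSpec:
    """The package's reference desk-scale cohort (only the seed varies)."""
    return CohortSpec(seed=seed)


def simulate_cohort(spec: CohortSpec) -> tuple[dict[str, dict[str, FCMatrix]], PlantedTruth]:
    """Simulate FCs for every (subject, condition); returns truth alongside.

    Deterministic given ``spec.seed``.  Subject loading jitter is drawn once
    per (subject, FN) and reused across conditions, so rest/task contrasts
    within a subject reflect only the planted condition effects plus
    sampling noise of the finite time series.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    part = spec.partition()
    sigma = part.sigma
    names = part.class_names
    beta = spec.between_coupling
    T = spec.n_timepoints
    n = spec.n_regions
    region_ids = tuple(f"R{i:03d}" for i in range(n))

    # ring position of each region within its FN
    theta = np.empty(n)
    for i in range(len(names)):
        members = np.flatnonzero(sigma == i)
        theta[members] = 2.0 * np.pi * np.arange(len(members)) / len(members)
    rho = spec.ring_share
    # per-region mixing weights onto (c_i, a_i, b_i)
    w_c = np.full(n, np.sqrt(1.0 - rho))
    w_a = np.sqrt(rho) * np.cos(theta)
    w_b = np.sqrt(rho) * np.sin(theta)

    subjects = [f"S{s:03d}" for s in range(spec.n_subjects)]
    cohort: dict[str, dict[str, FCMatrix]] = {}
    for subject in subjects:
        jitter = rng.normal(0.0, spec.subject_sd, size=len(names))
        cohort[subject] = {}
        for cond in spec.conditions:
            lam = np.empty(n)
            # jittered loadings clipped into the unit-variance region so an
            # extreme subject draw cannot produce a degenerate signal
            lam_hi = np.sqrt(1.0 - beta ** 2 - 0.02)
            for i, fn in enumerate(names):
                base = spec.within_coupling[fn] + jitter[i]
                base += spec.task_effects.get(cond, {}).get(fn, 0.0)
                lam[sigma == i] = min(max(base, 0.05), lam_hi)
            resid_var = 1.0 - lam ** 2 - beta ** 2
            fn_c = rng.standard_normal((len(names), T))
            fn_a = rng.standard_normal((len(names), T))
            fn_b = rng.standard_normal((len(names), T))
            global_factor = rng.standard_normal(T)
            noise = rng.standard_normal((n, T))
            fn_signal = (w_c[:, None] * fn_c[sigma]
                         + w_a[:, None] * fn_a[sigma]
                         + w_b[:, None] * fn_b[sigma])
            X = (lam[:, None] * fn_signal
                 + beta * global_factor[None, :]
                 + np.sqrt(resid_var)[:, None] * noise)
            cohort[subject][cond] = fc_from_timeseries(X, region_ids)

    effects = {c: dict(v) for c, v in spec.task_effects.items()}
    flat = [(c, fn, d) for c, per_fn in effects.items() for fn, d in per_fn.items()]
    if flat:
        cond, fn, _ = max(flat, key=lambda x: abs(x[2]))
    else:
        cond, fn = "", ""
    return cohort, PlantedTruth(most_perturbed_condition=cond,
                                most_perturbed_fn=fn, effects=effects)
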