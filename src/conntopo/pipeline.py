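"""End-to-end multi-level analysis pipeline.

Chains the five analysis levels over a cohort of per-subject, per-condition
functional connectomes: (1) group-average whole-brain distances between
conditions, (2) the same on the FN-consolidated super-graph, (3) FN-by-FN
distances within the resting condition (mesoscopic), (4) per-subject
consensus voting on the most distinct condition pair, and (5) per-subject
all-to-REST distance distributions compared between FNs by KL divergence,
with top-k FN-pair rankings per task.

The cohort is either read from a directory of FC matrices (one CSV per
subject/condition, named ``<subject>__<condition>.csv``, plus a partition
table) or simulated by the built-in generator.  All outputs are delimited
text plus a JSON run summary; reruns with the same inputs and seed are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import synthetic
from .connectome import (FCMatrix, Partition, consolidate_supergraph,
                         group_average_fc, induced_subnetwork)
from .filtration import PersistenceDiagram, persistence_from_fc
from .io import read_fc, read_partition, write_fc
from .landscape import (REST, ConditionSet, all_to_rest_distances,
                        condition_profiles, consensus_vote, kl_divergence,
                        pairwise_distance_table, top_k_fn_pairs)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("conntopo")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    When ``cohort_dir`` is None a synthetic cohort is simulated from the
    default desk-scale spec with ``seed``.  ``max_dim`` bounds the simplex
    dimension for group-level complexes (H_p up to max_dim - 1);
    ``individual_max_dim`` bounds the per-subject whole-brain complexes,
    which dominate runtime, and defaults to 2 (H0/H1).
    """

    output_dir: Path
    seed: int
    cohort_dir: Path | None = None
    partition_path: Path | None = None
    max_dim: int = 3
    individual_max_dim: int = 2
    q: float = 2.0
    metric_by_dim: Mapping[int, str] = field(
        default_factory=lambda: {0: "hausdorff_h0", 1: "wasserstein", 2: "wasserstein"})
    kl_bins: int = 10
    kl_pseudocount: float = 1.0
    top_k: int = 5
    write_cohort: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.cohort_dir is not None:
            self.cohort_dir = Path(self.cohort_dir)
            if self.partition_path is None:
                raise PipelineError("cohort_dir requires partition_path")
            self.partition_path = Path(self.partition_path)
            for p in (self.cohort_dir, self.partition_path):
                if not p.exists():
                    raise PipelineError(f"input path does not exist: {p}")
        if not self.q > 1:
            raise PipelineError(f"q must exceed 1, got {self.q}")
        if self.max_dim not in (1, 2, 3) or self.individual_max_dim not in (1, 2, 3):
            raise PipelineError("max_dim and individual_max_dim must be 1, 2 or 3")


def _load_cohort(cfg: RunConfig) -> tuple[dict[str, dict[str, FCMatrix]], Partition]:
    if cfg.cohort_dir is None:
        spec = synthetic.default_cohort_spec(cfg.seed)
        cohort, _truth = synthetic.simulate_cohort(spec)
        return cohort, spec.partition()
    cohort: dict[str, dict[str, FCMatrix]] = {}
    files = sorted(cfg.cohort_dir.glob("*.csv"))
    region_ids = None
    for f in files:
        stem = f.stem
        if "__" not in stem:
            continue
        subject, cond = stem.split("__", 1)
        fc = read_fc(f)
        region_ids = region_ids or fc.region_ids
        cohort.setdefault(subject, {})[cond] = fc
    if not cohort:
        raise PipelineError(f"no '<subject>__<condition>.csv' files in {cfg.cohort_dir}")
    part = read_partition(cfg.partition_path, region_ids)
    return cohort, part


def _condition_labels(cohort: Mapping[str, Mapping[str, FCMatrix]]) -> tuple[str, ...]:
    first = next(iter(cohort.values()))
    labels = tuple(first)
    for subject, per in cohort.items():
        if tuple(per) != labels:
            raise PipelineError(f"subject {subject} has conditions {tuple(per)}, "
                                f"expected {labels}")
    if REST not in labels:
        raise PipelineError("cohort must include a REST condition")
    return labels


def _diagram_map(fcs: Mapping[str, FCMatrix], max_dim: int,
                 n_cap: int = 200) -> dict[tuple[str, int], PersistenceDiagram]:
    out: dict[tuple[str, int], PersistenceDiagram] = {}
    for label, fc in fcs.items():
        for d in persistence_from_fc(fc, max_dim=max_dim, n_cap=n_cap):
            out[(label, d.dim)] = d
    return out


def _write_table(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every level and return (and write) the run summary."""
    logging.basicConfig(level=cfg.log_level)
    log.info("run parameters: q=%s metric_by_dim=%s kl_bins=%s kl_pseudocount=%s "
             "top_k=%s max_dim=%s individual_max_dim=%s seed=%s "
             "(argmax ties break lexicographically)",
             cfg.q, dict(cfg.metric_by_dim), cfg.kl_bins, cfg.kl_pseudocount,
             cfg.top_k, cfg.max_dim, cfg.individual_max_dim, cfg.seed)
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": cfg.seed,
        "parameters": {
            "q": cfg.q, "max_dim": cfg.max_dim,
            "individual_max_dim": cfg.individual_max_dim,
            "metric_by_dim": {str(k): v for k, v in cfg.metric_by_dim.items()},
            "kl_bins": cfg.kl_bins, "kl_pseudocount": cfg.kl_pseudocount,
            "top_k": cfg.top_k,
            "tie_rule": "lexicographically smallest label pair",
        },
        "levels": {},
    }
    long_rows: list[tuple] = []

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("load-cohort")
        cohort, part = _load_cohort(cfg)
        conditions = _condition_labels(cohort)
        subjects = sorted(cohort)
        summary["n_subjects"] = len(subjects)
        summary["conditions"] = list(conditions)
        summary["n_regions"] = next(iter(cohort.values()))[conditions[0]].n
        summary["functional_networks"] = list(part.class_names)
        if cfg.write_cohort and cfg.cohort_dir is None:
            cdir = out / "cohort"
            cdir.mkdir(parents=True, exist_ok=True)
            from .io import write_partition
            write_partition(part, cdir / "partition.csv")
            for s in subjects:
                for c in conditions:
                    write_fc(cohort[s][c], cdir / f"{s}__{c}.csv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage load-cohort failed: {exc}") from exc

    group = {c: group_average_fc([cohort[s][c] for s in subjects])
             for c in conditions}

    def analyse_condition_level(name: str, fcs: Mapping[str, FCMatrix],
                                max_dim: int, n_cap: int = 200) -> dict:
        dgms = _diagram_map(fcs, max_dim=max_dim, n_cap=n_cap)
        cset = ConditionSet(tuple(fcs), dgms)
        level: dict = {}
        for p in range(max_dim):
            tbl = pairwise_distance_table(cset, dim=p,
                                          metric=cfg.metric_by_dim.get(p), q=cfg.q)
            means, variances, pair = condition_profiles(tbl)
            _write_table(tbl.to_dataframe(), out / name / f"dist_h{p}.csv")
            _write_table(pd.DataFrame({"mean": means, "variance": variances}),
                         out / name / f"profiles_h{p}.csv")
            for i in range(len(tbl.labels)):
                for j in range(i + 1, len(tbl.labels)):
                    long_rows.append((name, tbl.labels[i], tbl.labels[j], p,
                                      tbl.metric, cfg.q, tbl.M[i, j]))
            n_classes = len(dgms[(tbl.labels[0], p)].persistent())
            level[f"h{p}"] = {
                "most_distinct_pair": list(pair),
                "mean_distance": {l: float(means[l]) for l in tbl.labels},
                "empty_diagrams": bool(all(
                    len(dgms[(l, p)].persistent()) == 0 for l in fcs)),
            }
            del n_classes
        return level

    try:
        stage("macroscopic-group")
        summary["levels"]["macroscopic_group"] = analyse_condition_level(
            "macroscopic", group, cfg.max_dim)
    except Exception as exc:
        raise PipelineError(f"stage macroscopic-group failed: {exc}") from exc

    try:
        stage("consolidated-group")
        supers = {c: consolidate_supergraph(group[c], part).normalized
                  for c in conditions}
        (out / "consolidated").mkdir(parents=True, exist_ok=True)
        write_fc(supers[REST], out / "consolidated" / "supergraph_REST.csv")
        summary["levels"]["consolidated_group"] = analyse_condition_level(
            "consolidated", supers, min(cfg.max_dim, part.k - 1) if part.k > 1 else 1)
    except Exception as exc:
        raise PipelineError(f"stage consolidated-group failed: {exc}") from exc

    try:
        stage("mesoscopic-rest")
        fn_fcs = {fn: induced_subnetwork(group[REST], part, fn)
                  for fn in part.class_names if len(part.members(fn)) >= 2}
        summary["levels"]["mesoscopic_rest"] = analyse_condition_level(
            "mesoscopic", fn_fcs, cfg.max_dim)
    except Exception as exc:
        raise PipelineError(f"stage mesoscopic-rest failed: {exc}") from exc

    try:
        stage("individual-consensus")
        level: dict = {}
        subject_tables: dict[int, list] = {p: [] for p in range(cfg.individual_max_dim)}
        for s in subjects:
            dgms = _diagram_map(cohort[s], max_dim=cfg.individual_max_dim)
            cset = ConditionSet(conditions, dgms)
            for p in range(cfg.individual_max_dim):
                subject_tables[p].append(pairwise_distance_table(
                    cset, dim=p, metric=cfg.metric_by_dim.get(p), q=cfg.q))
        for p, tables in subject_tables.items():
            votes = consensus_vote(tables)
            _write_table(votes.to_dataframe(), out / "consensus" / f"votes_h{p}.csv")
            level[f"h{p}"] = {
                "modal_pair": list(votes.modal_pair()),
                "n_subjects": votes.n_subjects,
            }
        summary["levels"]["individual_consensus"] = level
    except Exception as exc:
        raise PipelineError(f"stage individual-consensus failed: {exc}") from exc

    try:
        stage("all-to-rest-kl")
        meso_dims = min(cfg.max_dim, 3)
        fns = [fn for fn in part.class_names if len(part.members(fn)) >= 2]
        subject_diagrams: dict[str, dict] = {}
        for s in subjects:
            per: dict = {}
            for c in conditions:
                for fn in fns:
                    sub = induced_subnetwork(cohort[s][c], part, fn)
                    per[(fn, c)] = {d.dim: d for d in
                                    persistence_from_fc(sub, max_dim=meso_dims)}
            subject_diagrams[s] = per
        tasks = [c for c in conditions if c != REST]
        level = {}
        kl_rows = []
        for p in range(meso_dims):
            vectors = {(fn, t): all_to_rest_distances(
                subject_diagrams, fn, t, dim=p,
                metric=cfg.metric_by_dim.get(p), q=cfg.q) for fn in fns for t in tasks}
            top_by_task = {}
            for t in tasks:
                table = {}
                for a in fns:
                    for b in fns:
                        if a == b:
                            continue
                        v = kl_divergence(vectors[(a, t)], vectors[(b, t)],
                                          bins=cfg.kl_bins,
                                          pseudocount=cfg.kl_pseudocount)
                        table[(a, b)] = v
                        kl_rows.append((t, a, b, p, "kl", cfg.kl_bins, v))
                k = min(cfg.top_k, len(table))
                top = top_k_fn_pairs(table, k)
                top_by_task[t] = [
                    {"fn_pair": list(pair), "kl": val, "strength": strength}
                    for pair, val, strength in top]
            level[f"h{p}"] = {"top_pairs_by_task": top_by_task}
        _write_table(pd.DataFrame(
            kl_rows, columns=["task", "fn_a", "fn_b", "dim", "metric", "bins",
                              "value"]), out / "all_to_rest" / "kl_long.csv",
            index=False)
        summary["levels"]["all_to_rest_kl"] = level
    except Exception as exc:
        raise PipelineError(f"stage all-to-rest-kl failed: {exc}") from exc

    _write_table(pd.DataFrame(
        long_rows, columns=["level", "label_a", "label_b", "dim", "metric", "q",
                            "value"]), out / "distances_long.csv", index=False)
    summary["levels_completed"] = list(summary["levels"])
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %d levels", len(summary["levels"]))
    return summary
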