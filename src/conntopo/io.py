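"""Delimited-text readers and writers.

All formats are plain CSV so artifacts remain diff-able and portable:
FC matrices are square tables with region IDs as both header row and first
column; partitions are two-column (region_id, fn_label) tables; diagrams
are long tables with one (dim, birth, death, essential) row per interval.
Round-trips are lossless: floats are written with shortest-exact repr.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import ConnectomeError, FCMatrix, Partition
from .filtration import FiltrationError, PersistenceDiagram

__all__ = [
    "read_fc", "write_fc",
    "read_partition", "write_partition",
    "read_diagram", "write_diagram",
]


def write_fc(fc: FCMatrix, path: str | Path) -> None:
    pd.DataFrame(fc.W, index=fc.region_ids, columns=fc.region_ids).to_csv(path)


def read_fc(path: str | Path) -> FCMatrix:
    """Read a square FC table; symmetry checked to 1e-8 then averaged."""
    df = pd.read_csv(path, index_col=0)
    ids = tuple(str(i) for i in df.index)
    if tuple(str(c) for c in df.columns) != ids:
        raise ConnectomeError(f"{path}: row and column region IDs disagree")
    try:
        return FCMatrix(df.to_numpy(dtype=float), ids)
    except ConnectomeError as exc:
        raise ConnectomeError(f"{path}: {exc}") from None


def write_partition(part: Partition, path: str | Path) -> None:
    pd.DataFrame({
        "region_id": part.region_ids,
        "fn_label": [part.class_names[i] for i in part.sigma],
    }).to_csv(path, index=False)


def read_partition(path: str | Path,
                   region_ids: Sequence[str] | None = None) -> Partition:
    """Read a (region_id, fn_label) table.

    If ``region_ids`` is given (e.g. from an FC read alongside), rows are
    reordered to match it; unknown or missing regions raise a named error.
    """
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["region_id", "fn_label"]:
        raise ConnectomeError(
            f"{path}: expected columns (region_id, fn_label), got {list(df.columns)}")
    df = df.set_index("region_id")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ConnectomeError(f"{path}: duplicate region IDs {dupes}")
    if region_ids is not None:
        missing = [r for r in region_ids if r not in df.index]
        if missing:
            raise ConnectomeError(f"{path}: partition missing regions {missing}")
        extra = [r for r in df.index if r not in set(region_ids)]
        if extra:
            raise ConnectomeError(f"{path}: partition names unknown regions {extra}")
        df = df.loc[list(region_ids)]
    ids = tuple(df.index)
    labels = df["fn_label"].tolist()
    names = tuple(dict.fromkeys(labels))  # first-appearance order
    sigma = np.array([names.index(l) for l in labels])
    return Partition(sigma, names, ids)


def write_diagram(dgms: Sequence[PersistenceDiagram], path: str | Path) -> None:
    rows = []
    for d in dgms:
        for b, dth, e in zip(d.births, d.deaths, d.essential):
            rows.append((d.dim, b, dth, int(e)))
    pd.DataFrame(rows, columns=["dim", "birth", "death", "essential"]).to_csv(
        path, index=False)


def read_diagram(path: str | Path) -> list[PersistenceDiagram]:
    """Read diagrams back, one per homological dimension present."""
    df = pd.read_csv(path)
    expected = ["dim", "birth", "death", "essential"]
    if list(df.columns) != expected:
        raise FiltrationError(f"{path}: expected columns {expected}")
    if (df["death"] < df["birth"]).any():
        bad = df[df["death"] < df["birth"]].iloc[0]
        raise FiltrationError(
            f"{path}: interval with death {bad['death']} < birth {bad['birth']}")
    out = []
    for dim, grp in df.groupby("dim", sort=True):
        out.append(PersistenceDiagram(
            dim=int(dim),
            births=grp["birth"].to_numpy(dtype=float),
            deaths=grp["death"].to_numpy(dtype=float),
            essential=grp["essential"].to_numpy(dtype=bool),
        ))
    return out
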