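"""Readers and writers for cell-centre tables and analysis results.

Input dialect: one embryo per file (CSV, or first worksheet of an XLSX),
header row ``cell_id, x, y, z`` followed by optional intensity-channel
columns keyed by their header names. Overrides are a two-column CSV
``cell_id,new_class`` with class ``inside`` or ``outside``.

Outputs per embryo: a per-cell results CSV, a run-metadata JSON
(thresholds, counts, stage) and a labelled-point CSV for 3D plotting.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .model import (
    CellRecord,
    EmbryoDataset,
    OverrideSet,
    PositionClass,
    StageLabel,
    Subpopulation,
    Units,
    ValidationError,
)

__all__ = [
    "read_cell_table",
    "read_overrides",
    "write_results",
    "read_results_cells",
    "PER_CELL_COLUMNS",
]

_COORD_COLUMNS = ("x", "y", "z")

#: fixed column order of the per-cell results CSV
PER_CELL_COLUMNS = (
    "cell_id",
    "x",
    "y",
    "z",
    "class",
    "subpopulation",
    "n_neighbours",
    "pct_same_class_neighbours",
    "median_neighbour_distance",
)


def _load_frame(path: str | Path, fmt: str | None) -> pd.DataFrame:
    path = Path(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if fmt == "xlsx":
        return pd.read_excel(path, sheet_name=0)
    if fmt == "csv":
        return pd.read_csv(path)
    raise ValidationError(f"unsupported format {fmt!r} (expected 'csv' or 'xlsx')")


def read_cell_table(
    path: str | Path,
    format: str | None = None,
    units: Units | str = Units.UM,
    embryo_id: str | None = None,
    condition: str = "",
) -> EmbryoDataset:
    """Parse one embryo's cell-centre table into an :class:`EmbryoDataset`.

    Requires columns ``cell_id, x, y, z``; every further column is treated
    as an intensity channel keyed by its header. All position classes start
    unassigned; row order is preserved.
    """
    path = Path(path)
    frame = _load_frame(path, format)
    frame.columns = [str(c).strip() for c in frame.columns]
    if "cell_id" not in frame.columns:
        raise ValidationError(f"{path.name}: missing required column 'cell_id'")
    missing = [c for c in _COORD_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing coordinate column(s): {', '.join(missing)}")

    channels = [c for c in frame.columns if c not in ("cell_id", *_COORD_COLUMNS)]
    cells = []
    for row_no, row in enumerate(frame.itertuples(index=False, name=None), start=2):  # header = line 1
        values = dict(zip(frame.columns, row))
        coords = []
        for c in _COORD_COLUMNS:
            v = values[c]
            try:
                v = float(v)
            except (TypeError, ValueError):
                v = math.nan
            if not math.isfinite(v):
                raise ValidationError(f"{path.name}: non-finite coordinate {c!r} in row {row_no}")
            coords.append(v)
        intens = {}
        for ch in channels:
            v = values[ch]
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                intens[ch] = float(v)
        cells.append(CellRecord(cell_id=str(values["cell_id"]), position=tuple(coords), intensities=intens))

    return EmbryoDataset(
        embryo_id=embryo_id if embryo_id is not None else path.stem,
        cells=tuple(cells),
        units=Units(units),
        condition=condition,
    )


def read_overrides(path: str | Path) -> OverrideSet:
    """Read a manual-override CSV with header ``cell_id,new_class``."""
    frame = pd.read_csv(path)
    frame.columns = [str(c).strip() for c in frame.columns]
    for col in ("cell_id", "new_class"):
        if col not in frame.columns:
            raise ValidationError(f"{Path(path).name}: overrides need columns cell_id,new_class")
    entries = []
    for cid, cls in zip(frame["cell_id"], frame["new_class"]):
        cls = str(cls).strip().lower()
        if cls not in (PositionClass.INSIDE.value, PositionClass.OUTSIDE.value):
            raise ValidationError(f"override for {cid!r}: new_class must be inside or outside, got {cls!r}")
        entries.append((str(cid), PositionClass(cls)))
    return OverrideSet(entries=tuple(entries))


# ---------------------------------------------------------------------------
# Results output
# ---------------------------------------------------------------------------


def _per_cell_frame(dataset: EmbryoDataset, summary: Any | None) -> pd.DataFrame:
    per_cell = summary.per_cell if summary is not None else {}
    rows = []
    for cell in dataset.cells:
        stats = per_cell.get(cell.cell_id)
        rows.append(
            {
                "cell_id": cell.cell_id,
                "x": cell.position[0],
                "y": cell.position[1],
                "z": cell.position[2],
                "class": cell.position_class.value,
                "subpopulation": cell.subpopulation.value,
                "n_neighbours": stats.n_neighbours if stats is not None else None,
                "pct_same_class_neighbours": stats.pct_same_class if stats is not None else None,
                "median_neighbour_distance": stats.median_dist if stats is not None else None,
            }
        )
    return pd.DataFrame(rows, columns=list(PER_CELL_COLUMNS))


def write_results(
    dataset: EmbryoDataset,
    summary: Any | None,
    out_dir: str | Path,
    metadata: Mapping[str, Any] | None = None,
) -> dict[str, Path]:
    """Write per-cell CSV, per-embryo metadata JSON and labelled-point export.

    ``summary`` is a :class:`~iven.composition.NeighbourhoodSummary` or None
    for a classification-only run (neighbour columns are then left empty).
    Returns the paths written, keyed ``cells``, ``metadata``, ``points``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cells_path = out_dir / f"{dataset.embryo_id}_cells.csv"
    _per_cell_frame(dataset, summary).to_csv(cells_path, index=False)

    points_path = out_dir / f"{dataset.embryo_id}_points.csv"
    pd.DataFrame(
        {
            "cell_id": dataset.cell_ids,
            "x": [c.position[0] for c in dataset.cells],
            "y": [c.position[1] for c in dataset.cells],
            "z": [c.position[2] for c in dataset.cells],
            "class": [c.position_class.value for c in dataset.cells],
        }
    ).to_csv(points_path, index=False)

    meta: dict[str, Any] = {
        "embryo_id": dataset.embryo_id,
        "stage": dataset.stage_label.value,
        "condition": dataset.condition,
        "units": dataset.units.value,
        "n_cells": len(dataset),
        "n_outside": sum(c.position_class is PositionClass.OUTSIDE for c in dataset.cells),
        "n_inside": sum(c.position_class is PositionClass.INSIDE for c in dataset.cells),
    }
    if summary is not None and getattr(summary, "thresholds", None) is not None:
        meta["thresholds"] = summary.thresholds.as_dict()
    if metadata:
        meta.update(metadata)
    meta_path = out_dir / f"{dataset.embryo_id}_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    return {"cells": cells_path, "metadata": meta_path, "points": points_path}


def read_results_cells(path: str | Path) -> EmbryoDataset:
    """Re-read a per-cell results CSV back into an :class:`EmbryoDataset`.

    Round-trips cell_id, position, class and subpopulation (neighbour
    statistics live in the summary, not the dataset).
    """
    frame = pd.read_csv(path)
    cells = []
    for _, row in frame.iterrows():
        sub = row.get("subpopulation", "none")
        cells.append(
            CellRecord(
                cell_id=str(row["cell_id"]),
                position=(float(row["x"]), float(row["y"]), float(row["z"])),
                position_class=PositionClass(str(row["class"])),
                subpopulation=Subpopulation(str(sub) if not (isinstance(sub, float) and np.isnan(sub)) else "none"),
            )
        )
    return EmbryoDataset(embryo_id=Path(path).stem.removesuffix("_cells"), cells=tuple(cells))
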