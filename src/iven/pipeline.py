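"""End-to-end single-embryo and batch runs.

A run reads one cell-centre table, classifies inside/outside, applies any
manual overrides, assigns the developmental stage from the cell count,
builds the Delaunay graph, infers and applies the distance thresholds,
computes neighbour statistics and subpopulation labels, and writes the
per-cell, metadata and labelled-point outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io as iven_io
from .classify import convex_hull_classify, ellipsoid_classify
from .composition import (
    NeighbourhoodSummary,
    compare_groups_summary,
    label_subpopulations,
    neighbourhood_composition,
    summarise_embryo,
)
from .model import EmbryoDataset, OverrideSet, Units, assign_stage
from .neighbours import (
    ThresholdMode,
    correct_adjacency,
    delaunay_adjacency,
    infer_threshold,
    median_neighbour_distance,
    neighbour_counts,
    resolve_threshold_mode,
)

__all__ = ["RunConfig", "RunResult", "run_dataset", "run_single", "run_batch"]

logger = logging.getLogger("iven")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline parameters; defaults mirror the published analysis settings."""

    classifier: str = "hull"  # hull | ellipsoid
    k: float = 0.5
    threshold_mode: ThresholdMode = ThresholdMode.AUTO
    fixed_threshold: float | None = None
    overrides_path: str | Path | None = None
    out_dir: str | Path = "iven_out"
    units: Units = Units.UM
    condition: str = ""

    def __post_init__(self) -> None:
        if self.classifier not in ("hull", "ellipsoid"):
            raise ValueError(f"classifier must be 'hull' or 'ellipsoid', got {self.classifier!r}")
        if self.k < 0:
            raise ValueError(f"k must be ≥ 0, got {self.k}")
        mode = ThresholdMode(self.threshold_mode)
        object.__setattr__(self, "threshold_mode", mode)
        if mode is ThresholdMode.FIXED and self.fixed_threshold is None:
            raise ValueError("threshold_mode=fixed requires fixed_threshold")
        if mode is not ThresholdMode.FIXED and self.fixed_threshold is not None:
            raise ValueError("fixed_threshold only valid with threshold_mode=fixed")


@dataclass(frozen=True)
class RunResult:
    dataset: EmbryoDataset
    summary: NeighbourhoodSummary
    paths: dict = field(default_factory=dict)


def run_dataset(
    dataset: EmbryoDataset,
    config: RunConfig = RunConfig(),
    overrides: OverrideSet | None = None,
) -> RunResult:
    """Run classification and neighbourhood analysis on an in-memory dataset."""
    if config.classifier == "hull":
        dataset = convex_hull_classify(dataset)
    else:
        dataset, _ = ellipsoid_classify(dataset)
    if overrides is not None:
        dataset = overrides.apply(dataset)
    dataset = assign_stage(dataset)

    graph = delaunay_adjacency(dataset)
    labels = dataset.classes()
    mode = resolve_threshold_mode(config.threshold_mode, dataset.stage_label)
    spec = infer_threshold(graph, labels, k=config.k, mode=mode, fixed_threshold=config.fixed_threshold)
    corrected = correct_adjacency(graph, labels, spec)

    counts = neighbour_counts(corrected)
    comp = neighbourhood_composition(corrected, labels)
    med = median_neighbour_distance(corrected)
    subpops = label_subpopulations(corrected, labels, comp)
    dataset = dataset.with_subpopulations(subpops)

    summary = summarise_embryo(dataset, corrected, spec, counts, comp, med, subpops)
    logger.info(
        "embryo %s: stage %s, %d cells (%d outside / %d inside), T_in=%.3g T_out=%.3g",
        dataset.embryo_id, dataset.stage_label.value, len(dataset),
        int(summary.per_embryo["n_outside"]), int(summary.per_embryo["n_inside"]),
        spec.t_inside, spec.t_outside,
    )
    return RunResult(dataset=dataset, summary=summary, paths={})


def run_single(path: str | Path, config: RunConfig = RunConfig()) -> RunResult:
    """Full run on one input table; writes outputs under config.out_dir."""
    dataset = iven_io.read_cell_table(path, units=config.units, condition=config.condition)
    overrides = iven_io.read_overrides(config.overrides_path) if config.overrides_path else None
    result = run_dataset(dataset, config, overrides)
    paths = iven_io.write_results(
        result.dataset,
        result.summary,
        config.out_dir,
        metadata={"k": config.k, "classifier": config.classifier,
                  "per_embryo": result.summary.per_embryo},
    )
    return RunResult(dataset=result.dataset, summary=result.summary, paths=paths)


def run_batch(paths: Sequence[str | Path], config: RunConfig = RunConfig()) -> dict:
    """Independent per-embryo runs plus a combined per-stage/condition report.

    One failing file does not abort the batch; its error is recorded in the
    returned status map. The combined report aggregates per-embryo summary
    rows grouped by (stage, condition), in deterministic order.
    """
    if not paths:
        raise ValueError("no input files matched")
    statuses: dict[str, str] = {}
    results: list[RunResult] = []
    for p in sorted(str(x) for x in paths):
        try:
            results.append(run_single(p, config))
            statuses[p] = "ok"
        except Exception as exc:  # isolate failures per file
            logger.error("failed on %s: %s", p, exc)
            statuses[p] = f"error: {exc}"

    rows = []
    for r in results:
        row = {
            "embryo_id": r.dataset.embryo_id,
            "stage": r.dataset.stage_label.value,
            "condition": r.dataset.condition,
        }
        row.update(r.summary.per_embryo)
        rows.append(row)
    per_embryo = pd.DataFrame(rows)
    if not per_embryo.empty:
        per_embryo = per_embryo.sort_values(["stage", "condition", "embryo_id"]).reset_index(drop=True)
        grouped = (
            per_embryo.drop(columns=["embryo_id"])
            .groupby(["stage", "condition"], sort=True)
            .mean()
            .reset_index()
        )
    else:
        grouped = pd.DataFrame()

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_embryo.to_csv(out_dir / "batch_per_embryo.csv", index=False)
    grouped.to_csv(out_dir / "batch_per_stage.csv", index=False)
    status_frame = pd.DataFrame(sorted(statuses.items()), columns=["path", "status"])
    status_frame.to_csv(out_dir / "batch_status.csv", index=False)
    return {"statuses": statuses, "results": results, "per_embryo": per_embryo, "per_stage": grouped}
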