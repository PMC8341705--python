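"""Neighbourhood composition, subpopulation labels and aggregates.

A cell's neighbourhood composition is the percentage of its corrected-DT
neighbours sharing its own inside/outside class. Composition 100 singles
out the architecturally extreme subpopulations: outside cells with
exclusively outside neighbours are mural trophectoderm (they line the
cavity), the remaining outside cells polar trophectoderm; inside cells
entirely surrounded by inside cells are deep ICM, the rest plain ICM.
Cells left with zero neighbours after correction have undefined
composition and are labelled ``none``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import EmbryoDataset, PositionClass, Subpopulation, ValidationError
from .neighbours import NeighbourGraph, ThresholdSpec

__all__ = [
    "CellStats",
    "NeighbourhoodSummary",
    "neighbourhood_composition",
    "label_subpopulations",
    "pct_mural",
    "frequency_distribution",
    "average_frequency_distribution",
    "normalize_intensity",
    "summarise_embryo",
    "compare_groups_summary",
]

logger = logging.getLogger("iven")


def neighbourhood_composition(
    graph: NeighbourGraph, labels: Mapping[str, PositionClass]
) -> dict[str, float]:
    """Per cell: 100 × (neighbours of the same class) / (neighbours).

    NaN for cells with zero neighbours (composition undefined).
    """
    comp: dict[str, float] = {}
    same = {n: 0 for n in graph.nodes}
    total = {n: 0 for n in graph.nodes}
    for a, b in graph.edge_length:
        total[a] += 1
        total[b] += 1
        if labels[a] is labels[b]:
            same[a] += 1
            same[b] += 1
    for n in graph.nodes:
        comp[n] = 100.0 * same[n] / total[n] if total[n] else float("nan")
    return comp


def label_subpopulations(
    graph: NeighbourGraph,
    labels: Mapping[str, PositionClass],
    composition: Mapping[str, float] | None = None,
) -> dict[str, Subpopulation]:
    """Mural/polar TE and deep/plain ICM labels from composition.

    outside + composition 100 → mural_te; other outside → polar_te;
    inside + composition 100 → deep_icm; other inside → icm;
    zero-neighbour cells → none.
    """
    if composition is None:
        composition = neighbourhood_composition(graph, labels)
    out: dict[str, Subpopulation] = {}
    for n in graph.nodes:
        c = composition[n]
        if isinstance(c, float) and math.isnan(c):
            out[n] = Subpopulation.NONE
        elif labels[n] is PositionClass.OUTSIDE:
            out[n] = Subpopulation.MURAL_TE if c == 100.0 else Subpopulation.POLAR_TE
        elif labels[n] is PositionClass.INSIDE:
            out[n] = Subpopulation.DEEP_ICM if c == 100.0 else Subpopulation.ICM
        else:
            out[n] = Subpopulation.NONE
    return out


def pct_mural(subpops: Mapping[str, Subpopulation]) -> float:
    """Mural share of the TE: 100 × #mural / (#mural + #polar); NaN if no TE."""
    n_mural = sum(1 for s in subpops.values() if s is Subpopulation.MURAL_TE)
    n_polar = sum(1 for s in subpops.values() if s is Subpopulation.POLAR_TE)
    if n_mural + n_polar == 0:
        return float("nan")
    return 100.0 * n_mural / (n_mural + n_polar)


def frequency_distribution(
    counts: Mapping[str, int], group: Iterable[str] | None = None
) -> dict[int, float]:
    """Relative frequency of each neighbour count within a group of cells."""
    ids = list(group) if group is not None else list(counts)
    if not ids:
        return {}
    values = [counts[i] for i in ids]
    hist: dict[int, float] = {}
    for v in values:
        hist[v] = hist.get(v, 0.0) + 1.0
    return {k: v / len(values) for k, v in sorted(hist.items())}


def average_frequency_distribution(
    histograms: Sequence[Mapping[int, float]],
) -> tuple[dict[int, float], dict[int, float]]:
    """Per-bin mean and SEM across embryo histograms (missing bins = 0).

    With a single embryo the SEM is reported as 0 (with a warning) so the
    plotting contract always receives a number.
    """
    if not histograms:
        raise ValueError("need at least one histogram")
    bins = sorted({b for h in histograms for b in h})
    n = len(histograms)
    if n == 1:
        logger.warning("average_frequency_distribution: single embryo, SEM reported as 0")
    mean: dict[int, float] = {}
    sem: dict[int, float] = {}
    for b in bins:
        vals = np.asarray([h.get(b, 0.0) for h in histograms], dtype=float)
        mean[b] = float(vals.mean())
        sem[b] = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, sem


def normalize_intensity(
    dataset: EmbryoDataset, channel: str, reference: str
) -> dict[str, float]:
    """Attenuation-corrected, per-embryo max-normalised channel intensity.

    Each cell's channel value is divided by its reference (nuclear dye)
    intensity to correct for depth attenuation, then the ratios are scaled
    by the embryo-wide maximum so the brightest cell reads exactly 1.
    """
    corrected: dict[str, float] = {}
    bad: list[str] = []
    for cell in dataset.cells:
        ch = cell.intensities.get(channel)
        ref = cell.intensities.get(reference)
        if ch is None or ref is None or ref <= 0:
            bad.append(cell.cell_id)
            continue
        corrected[cell.cell_id] = ch / ref
    if bad:
        raise ValidationError(
            f"channel {channel!r}/{reference!r}: missing or non-positive reference intensity "
            "for cells: " + ", ".join(bad)
        )
    peak = max(corrected.values())
    return {cid: v / peak for cid, v in corrected.items()}


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellStats:
    n_neighbours: int
    pct_same_class: float  # NaN if 0 neighbours
    median_dist: float     # NaN if 0 neighbours


@dataclass(frozen=True)
class NeighbourhoodSummary:
    """Per-cell statistics plus per-embryo aggregates for one embryo."""

    embryo_id: str
    per_cell: dict[str, CellStats]
    thresholds: ThresholdSpec | None
    frequency: dict[str, dict[int, float]] = field(default_factory=dict)
    per_embryo: dict[str, float] = field(default_factory=dict)


def _nanstat(values: list[float], fn) -> float:
    vals = [v for v in values if not math.isnan(v)]
    return float(fn(vals)) if vals else float("nan")


def summarise_embryo(
    dataset: EmbryoDataset,
    graph: NeighbourGraph,
    thresholds: ThresholdSpec | None,
    counts: Mapping[str, int],
    composition: Mapping[str, float],
    median_dist: Mapping[str, float],
    subpops: Mapping[str, Subpopulation],
) -> NeighbourhoodSummary:
    """Assemble the per-cell table and per-embryo aggregates.

    Aggregates report both the mean and median neighbour count per class,
    the mural share of the TE, the deep-ICM fraction of inside cells, and
    class-wise medians of composition and neighbour distance. Cells with
    zero neighbours are excluded from composition/distance aggregates.
    """
    labels = dataset.classes()
    per_cell = {
        cid: CellStats(
            n_neighbours=int(counts[cid]),
            pct_same_class=float(composition[cid]),
            median_dist=float(median_dist[cid]),
        )
        for cid in dataset.cell_ids
    }
    inside = [c for c in dataset.cell_ids if labels[c] is PositionClass.INSIDE]
    outside = [c for c in dataset.cell_ids if labels[c] is PositionClass.OUTSIDE]
    n_deep = sum(1 for c in inside if subpops[c] is Subpopulation.DEEP_ICM)

    per_embryo = {
        "n_cells": float(len(dataset)),
        "n_inside": float(len(inside)),
        "n_outside": float(len(outside)),
        "mean_inside_count": _nanstat([float(counts[c]) for c in inside], np.mean),
        "mean_outside_count": _nanstat([float(counts[c]) for c in outside], np.mean),
        "median_inside_count": _nanstat([float(counts[c]) for c in inside], np.median),
        "median_outside_count": _nanstat([float(counts[c]) for c in outside], np.median),
        "pct_mural_of_outside": pct_mural(subpops),
        "pct_deep_of_inside": (100.0 * n_deep / len(inside)) if inside else float("nan"),
        "median_composition_inside": _nanstat([composition[c] for c in inside], np.median),
        "median_composition_outside": _nanstat([composition[c] for c in outside], np.median),
        "median_dist_inside": _nanstat([median_dist[c] for c in inside], np.median),
        "median_dist_outside": _nanstat([median_dist[c] for c in outside], np.median),
    }
    frequency = {
        "inside": frequency_distribution(counts, inside),
        "outside": frequency_distribution(counts, outside),
        "all": frequency_distribution(counts),
    }
    return NeighbourhoodSummary(
        embryo_id=dataset.embryo_id,
        per_cell=per_cell,
        thresholds=thresholds,
        frequency=frequency,
        per_embryo=per_embryo,
    )


def compare_groups_summary(
    summaries_by_condition: Mapping[str, Sequence[NeighbourhoodSummary]],
) -> pd.DataFrame:
    """Per-condition medians/IQRs of the inside-cell statistics.

    One row per condition: median and IQR (across embryos) of inside-cell
    neighbour counts, compositions and median neighbour distances, plus
    the deep-ICM fraction. Purely descriptive — no hypothesis testing.
    """
    rows = []
    for condition in sorted(summaries_by_condition):
        summaries = summaries_by_condition[condition]

        def _agg(key: str) -> tuple[float, float]:
            vals = [s.per_embryo[key] for s in summaries if not math.isnan(s.per_embryo[key])]
            if not vals:
                return float("nan"), float("nan")
            q25, q75 = np.percentile(vals, [25, 75])
            return float(np.median(vals)), float(q75 - q25)

        med_cnt, iqr_cnt = _agg("mean_inside_count")
        med_comp, iqr_comp = _agg("median_composition_inside")
        med_dist, iqr_dist = _agg("median_dist_inside")
        med_deep, iqr_deep = _agg("pct_deep_of_inside")
        rows.append(
            {
                "condition": condition,
                "n_embryos": len(summaries),
                "median_inside_count": med_cnt,
                "iqr_inside_count": iqr_cnt,
                "median_composition_inside": med_comp,
                "iqr_composition_inside": iqr_comp,
                "median_dist_inside": med_dist,
                "iqr_dist_inside": iqr_dist,
                "median_pct_deep_icm": med_deep,
                "iqr_pct_deep_icm": iqr_deep,
            }
        )
    return pd.DataFrame(rows)
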