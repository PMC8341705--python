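"""Corrected Delaunay neighbourhood graphs.

Candidate neighbours are the edges of the 3D Delaunay triangulation (DT)
of the cell centres. The raw DT joins cells across the blastocyst cavity
("untrue" neighbours), so edges longer than a distance threshold are
removed. Thresholds are inferred per embryo from the neighbour-distance
distribution as

    T = P75 + k · IQR            (default k = 0.5)

with P75 the 75th percentile and IQR the interquartile range, both by
linear interpolation between order statistics. From the 32-cell stage
onwards separate thresholds are used for inside and outside cells: the
outside threshold applies to outside–outside edges, the inside threshold
to every edge with at least one inside endpoint (including mixed
inside–outside pairs). Edges at exactly the threshold are kept.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .model import EmbryoDataset, GeometryError, PositionClass, StageLabel

__all__ = [
    "Edge",
    "NeighbourGraph",
    "ThresholdMode",
    "ThresholdSpec",
    "delaunay_adjacency",
    "infer_threshold",
    "correct_adjacency",
    "neighbour_counts",
    "median_neighbour_distance",
    "resolve_threshold_mode",
]

logger = logging.getLogger("iven")

Edge = tuple[str, str]


def _edge(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class NeighbourGraph:
    """Undirected adjacency over cells with per-edge Euclidean lengths."""

    nodes: tuple[str, ...]
    edge_length: Mapping[Edge, float]
    corrected: bool = False

    @property
    def edges(self) -> set[Edge]:
        return set(self.edge_length)

    def degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for a, b in self.edge_length:
            deg[a] += 1
            deg[b] += 1
        return deg

    def incident_lengths(self) -> dict[str, list[float]]:
        inc: dict[str, list[float]] = {n: [] for n in self.nodes}
        for (a, b), d in self.edge_length.items():
            inc[a].append(d)
            inc[b].append(d)
        return inc

    def neighbours_of(self, cell_id: str) -> set[str]:
        out = set()
        for a, b in self.edge_length:
            if a == cell_id:
                out.add(b)
            elif b == cell_id:
                out.add(a)
        return out


class ThresholdMode(str, enum.Enum):
    AUTO = "auto"      # split at ≥ 32-cell stage, single before
    SINGLE = "single"
    SPLIT = "split"
    FIXED = "fixed"


@dataclass(frozen=True)
class ThresholdSpec:
    """Per-embryo distance thresholds T = P75 + k·IQR (input units)."""

    k: float
    mode: ThresholdMode
    t_inside: float
    t_outside: float
    p75_inside: float = float("nan")
    iqr_inside: float = float("nan")
    p75_outside: float = float("nan")
    iqr_outside: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "mode": self.mode.value,
            "t_inside": self.t_inside,
            "t_outside": self.t_outside,
            "p75_inside": self.p75_inside,
            "iqr_inside": self.iqr_inside,
            "p75_outside": self.p75_outside,
            "iqr_outside": self.iqr_outside,
        }


def delaunay_adjacency(dataset: EmbryoDataset) -> NeighbourGraph:
    """Uncorrected neighbour graph: union of edges of all DT tetrahedra."""
    dataset.require_triangulable()
    points = dataset.coordinates()
    ids = dataset.cell_ids
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise GeometryError(
            f"embryo {dataset.embryo_id!r}: degenerate point set for triangulation: {exc}"
        ) from exc
    lengths: dict[Edge, float] = {}
    for simplex in tri.simplices:
        for i in range(4):
            for j in range(i + 1, 4):
                a, b = int(simplex[i]), int(simplex[j])
                e = _edge(ids[a], ids[b])
                if e not in lengths:
                    lengths[e] = float(np.linalg.norm(points[a] - points[b]))
    return NeighbourGraph(nodes=tuple(ids), edge_length=lengths, corrected=False)


def _p75_iqr(lengths: np.ndarray) -> tuple[float, float]:
    p25, p75 = np.percentile(lengths, [25, 75])  # linear interpolation
    return float(p75), float(p75 - p25)


def resolve_threshold_mode(mode: ThresholdMode, stage: StageLabel) -> ThresholdMode:
    """AUTO resolves to split from the 32-cell stage onwards, else single."""
    if mode is not ThresholdMode.AUTO:
        return mode
    if stage in (StageLabel.S32, StageLabel.S64, StageLabel.S128):
        return ThresholdMode.SPLIT
    return ThresholdMode.SINGLE


def infer_threshold(
    graph: NeighbourGraph,
    labels: Mapping[str, PositionClass],
    k: float = 0.5,
    mode: ThresholdMode = ThresholdMode.SINGLE,
    fixed_threshold: float | None = None,
) -> ThresholdSpec:
    """Infer distance thresholds from the uncorrected edge-length distribution.

    single: one pooled distribution, T_inside = T_outside.
    split:  outside distribution = outside–outside edge lengths, inside
            distribution = inside–inside edge lengths. Mixed edges enter
            neither distribution (in cavity geometries they include the
            long "untrue" cavity-spanning connections whose removal is the
            point of the threshold; pooling them into a class distribution
            would drag its P75 into that tail). They are still policed by
            the inside threshold when the correction is applied. An empty
            class distribution falls back to the pooled one with a warning.
    fixed:  the user-supplied threshold passes through.
    """
    if k < 0:
        raise ValueError(f"k must be ≥ 0, got {k}")
    if mode is ThresholdMode.FIXED:
        if fixed_threshold is None:
            raise ValueError("fixed mode requires a fixed_threshold value")
        return ThresholdSpec(k=k, mode=mode, t_inside=float(fixed_threshold), t_outside=float(fixed_threshold))
    if mode is ThresholdMode.AUTO:
        raise ValueError("resolve AUTO against the embryo stage before inferring thresholds")

    all_lengths = np.asarray(list(graph.edge_length.values()), dtype=float)
    if all_lengths.size == 0:
        raise ValueError("cannot infer a threshold from a graph with no edges")
    p75_all, iqr_all = _p75_iqr(all_lengths)

    if mode is ThresholdMode.SINGLE:
        t = p75_all + k * iqr_all
        return ThresholdSpec(
            k=k, mode=mode, t_inside=t, t_outside=t,
            p75_inside=p75_all, iqr_inside=iqr_all,
            p75_outside=p75_all, iqr_outside=iqr_all,
        )

    # split mode
    out_lengths, in_lengths = [], []
    for (a, b), d in graph.edge_length.items():
        if labels[a] is PositionClass.OUTSIDE and labels[b] is PositionClass.OUTSIDE:
            out_lengths.append(d)
        elif labels[a] is PositionClass.INSIDE and labels[b] is PositionClass.INSIDE:
            in_lengths.append(d)

    def _class_stats(vals: list[float], name: str) -> tuple[float, float]:
        if not vals:
            msg = f"no edges in the {name} distance distribution; falling back to pooled threshold"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=3)
            return p75_all, iqr_all
        return _p75_iqr(np.asarray(vals))

    p75_out, iqr_out = _class_stats(out_lengths, "outside")
    p75_in, iqr_in = _class_stats(in_lengths, "inside")
    return ThresholdSpec(
        k=k, mode=mode,
        t_inside=p75_in + k * iqr_in, t_outside=p75_out + k * iqr_out,
        p75_inside=p75_in, iqr_inside=iqr_in,
        p75_outside=p75_out, iqr_outside=iqr_out,
    )


def correct_adjacency(
    graph: NeighbourGraph,
    labels: Mapping[str, PositionClass],
    spec: ThresholdSpec,
) -> NeighbourGraph:
    """Drop over-threshold edges; class-specific rule, inclusive at T.

    Outside–outside edges are kept iff length ≤ T_outside; every edge with
    at least one inside endpoint iff length ≤ T_inside. The node set is
    unchanged — cells may end up with zero neighbours.
    """
    kept: dict[Edge, float] = {}
    for (a, b), d in graph.edge_length.items():
        both_outside = labels[a] is PositionClass.OUTSIDE and labels[b] is PositionClass.OUTSIDE
        limit = spec.t_outside if both_outside else spec.t_inside
        if d <= limit:
            kept[(a, b)] = d
    return NeighbourGraph(nodes=graph.nodes, edge_length=kept, corrected=True)


def neighbour_counts(graph: NeighbourGraph) -> dict[str, int]:
    """Neighbour count per cell = degree in the (corrected) graph."""
    return graph.degree()


def median_neighbour_distance(graph: NeighbourGraph) -> dict[str, float]:
    """Per-cell median incident edge length; NaN for isolated cells."""
    return {
        n: (float(np.median(ls)) if ls else float("nan"))
        for n, ls in graph.incident_lengths().items()
    }
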