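"""Core data model for embryo cell-centre datasets.

The unit of analysis is an :class:`EmbryoDataset`: an ordered collection of
:class:`CellRecord` objects, each holding a cell identifier, a 3D nuclear
centre, optional per-channel fluorescence intensities, an inside/outside
position class and (after neighbourhood analysis) a subpopulation label
(mural/polar trophectoderm, deep ICM).

Coordinates are taken as given (μm or pixels, consistent within one embryo);
no unit conversion is performed, and all derived distances and thresholds
inherit the input units.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PositionClass",
    "Subpopulation",
    "StageLabel",
    "Units",
    "CellRecord",
    "EmbryoDataset",
    "OverrideSet",
    "ValidationError",
    "GeometryError",
    "STAGES",
    "stage_window",
    "assign_stage",
]


class ValidationError(ValueError):
    """Raised when an input table or override set violates the data contract."""


class GeometryError(ValueError):
    """Raised when a point set is too small or too degenerate for 3D geometry."""


class PositionClass(str, enum.Enum):
    INSIDE = "inside"
    OUTSIDE = "outside"
    UNASSIGNED = "unassigned"


class Subpopulation(str, enum.Enum):
    ICM = "icm"
    DEEP_ICM = "deep_icm"
    MURAL_TE = "mural_te"
    POLAR_TE = "polar_te"
    NONE = "none"


class StageLabel(str, enum.Enum):
    S8 = "8"
    S16 = "16"
    S32 = "32"
    S64 = "64"
    S128 = "128"
    UNASSIGNED = "unassigned"


class Units(str, enum.Enum):
    UM = "um"
    PX = "px"


#: subpopulations only meaningful for a given position class
_OUTSIDE_SUBPOPS = {Subpopulation.MURAL_TE, Subpopulation.POLAR_TE}
_INSIDE_SUBPOPS = {Subpopulation.ICM, Subpopulation.DEEP_ICM}


@dataclass(frozen=True)
class CellRecord:
    """One cell: identifier, 3D centre, optional channel intensities, labels."""

    cell_id: str
    position: tuple[float, float, float]
    intensities: Mapping[str, float] = field(default_factory=dict)
    position_class: PositionClass = PositionClass.UNASSIGNED
    subpopulation: Subpopulation = Subpopulation.NONE

    def __post_init__(self) -> None:
        pos = tuple(float(v) for v in self.position)
        if len(pos) != 3 or not all(math.isfinite(v) for v in pos):
            raise ValidationError(
                f"cell {self.cell_id!r}: position must have 3 finite components, got {self.position!r}"
            )
        object.__setattr__(self, "position", pos)
        if self.subpopulation in _OUTSIDE_SUBPOPS and self.position_class is not PositionClass.OUTSIDE:
            raise ValidationError(
                f"cell {self.cell_id!r}: subpopulation {self.subpopulation.value} requires position_class=outside"
            )
        if self.subpopulation in _INSIDE_SUBPOPS and self.position_class is not PositionClass.INSIDE:
            raise ValidationError(
                f"cell {self.cell_id!r}: subpopulation {self.subpopulation.value} requires position_class=inside"
            )


@dataclass(frozen=True)
class EmbryoDataset:
    """An embryo's cells plus metadata (stage, condition, units)."""

    embryo_id: str
    cells: tuple[CellRecord, ...]
    stage_label: StageLabel = StageLabel.UNASSIGNED
    condition: str = ""
    units: Units = Units.UM

    def __post_init__(self) -> None:
        cells = tuple(self.cells)
        object.__setattr__(self, "cells", cells)
        seen_ids: set[str] = set()
        seen_pos: set[tuple[float, float, float]] = set()
        for cell in cells:
            if cell.cell_id in seen_ids:
                raise ValidationError(f"duplicate cell_id: {cell.cell_id!r}")
            seen_ids.add(cell.cell_id)
            if cell.position in seen_pos:
                raise ValidationError(
                    f"duplicate coordinates {cell.position} (cell {cell.cell_id!r}); "
                    "identical centres are degenerate for triangulation"
                )
            seen_pos.add(cell.position)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]

    def coordinates(self) -> np.ndarray:
        """(n, 3) float array of cell centres, in input order."""
        return np.asarray([c.position for c in self.cells], dtype=float)

    def classes(self) -> dict[str, PositionClass]:
        return {c.cell_id: c.position_class for c in self.cells}

    def cell(self, cell_id: str) -> CellRecord:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)

    def with_cells(self, cells: Iterable[CellRecord]) -> "EmbryoDataset":
        return replace(self, cells=tuple(cells))

    def with_classes(self, classes: Mapping[str, PositionClass]) -> "EmbryoDataset":
        """Return a copy with position classes replaced (subpopulations reset)."""
        new_cells = []
        for c in self.cells:
            cls = classes.get(c.cell_id, c.position_class)
            new_cells.append(replace(c, position_class=cls, subpopulation=Subpopulation.NONE))
        return self.with_cells(new_cells)

    def with_subpopulations(self, subpops: Mapping[str, Subpopulation]) -> "EmbryoDataset":
        new_cells = [
            replace(c, subpopulation=subpops.get(c.cell_id, c.subpopulation)) for c in self.cells
        ]
        return self.with_cells(new_cells)

    def require_triangulable(self) -> None:
        if len(self.cells) < 5:
            raise GeometryError(
                f"embryo {self.embryo_id!r}: at least 5 cells are required for 3D analysis, got {len(self.cells)}"
            )


@dataclass(frozen=True)
class OverrideSet:
    """Manual reclassification entries: (cell_id, new position class).

    File-based replacement for the interactive correction step: after the
    automatic convex-hull classification, listed cells are forced to the
    stated class.
    """

    entries: tuple[tuple[str, PositionClass], ...] = ()

    def apply(self, dataset: EmbryoDataset) -> EmbryoDataset:
        known = set(dataset.cell_ids)
        unknown = [cid for cid, _ in self.entries if cid not in known]
        if unknown:
            raise ValidationError("unknown cell_id: " + ", ".join(sorted(set(unknown))))
        mapping = {cid: cls for cid, cls in self.entries}
        return dataset.with_classes(mapping)


# ---------------------------------------------------------------------------
# Stage assignment
# ---------------------------------------------------------------------------

STAGES: tuple[int, ...] = (8, 16, 32, 64, 128)


def stage_window(stage: int) -> tuple[int, int]:
    """Inclusive cell-count window for a nominal stage: |n − s| ≤ round(0.1·s).

    The tolerance generalises the "within 10% of cells of the desired stage"
    selection rule (e.g. 32-cell embryos have 32 ± 3 cells): 8→±1, 16→±2,
    32→±3, 64→±6, 128→±13.
    """
    tol = round(0.1 * stage)
    return stage - tol, stage + tol


def assign_stage(dataset: EmbryoDataset) -> EmbryoDataset:
    """Set stage_label from the cell count; unassigned if no window matches.

    Pure function of the cell count. The five stage windows are pairwise
    disjoint, so at most one can match.
    """
    n = len(dataset)
    matches = [s for s in STAGES if stage_window(s)[0] <= n <= stage_window(s)[1]]
    label = StageLabel(str(matches[0])) if len(matches) == 1 else StageLabel.UNASSIGNED
    return replace(dataset, stage_label=label)


def apply_overrides(dataset: EmbryoDataset, overrides: OverrideSet) -> EmbryoDataset:
    """Apply manual class overrides; idempotent; unknown IDs are an error."""
    return overrides.apply(dataset)
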