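"""Inside/outside cell classification.

The primary classifier takes the 3D convex hull of the nuclear centres:
cells that are vertices of the hull — the cells "generating" it — are
outside (trophectoderm-like) cells, every enclosed cell is inside
(ICM-like). Cells that happen to lie on a hull facet without being
vertices (measure zero for real data) are classified inside.

A deliberately simple ellipsoid comparator is also provided: an
axis-aligned algebraic least-squares ellipsoid is fitted to the centres
and each cell scored

    ν = ((x − o_x)/a)² + ((y − o_y)/b)² + ((z − o_z)/c)²

with ν ≥ 1 ⇒ outside. The hull is the default because it tolerates
deformed, non-ellipsoidal embryos.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .model import EmbryoDataset, GeometryError, PositionClass

__all__ = [
    "EllipsoidFit",
    "FitError",
    "convex_hull_classify",
    "fit_ellipsoid",
    "ellipsoid_classify",
    "compare_classifiers",
]


class FitError(ValueError):
    """Raised when the ellipsoid fit is infeasible or degenerate."""


def convex_hull_classify(dataset: EmbryoDataset) -> EmbryoDataset:
    """Label hull-vertex cells outside and all remaining cells inside."""
    dataset.require_triangulable()
    points = dataset.coordinates()
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise GeometryError(
            f"embryo {dataset.embryo_id!r}: degenerate point set (coplanar/collinear?): {exc}"
        ) from exc
    vertex_rows = set(int(i) for i in hull.vertices)
    classes = {
        cid: (PositionClass.OUTSIDE if i in vertex_rows else PositionClass.INSIDE)
        for i, cid in enumerate(dataset.cell_ids)
    }
    return dataset.with_classes(classes)


@dataclass(frozen=True)
class EllipsoidFit:
    """Axis-aligned ellipsoid: centre (o_x, o_y, o_z), radii (a, b, c) > 0."""

    centre: tuple[float, float, float]
    radii: tuple[float, float, float]

    def score(self, points: np.ndarray) -> np.ndarray:
        """ν per point; 0 at the centre, 1 on the fitted surface, >1 beyond."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d = (p - np.asarray(self.centre)) / np.asarray(self.radii)
        return np.einsum("ij,ij->i", d, d)


def fit_ellipsoid(points: np.ndarray) -> EllipsoidFit:
    """Least-squares algebraic fit of an axis-aligned ellipsoid.

    Solves A x² + B y² + C z² + 2D x + 2E y + 2F z = 1 in the least-squares
    sense and converts to centre/radii form. Points lying exactly on an
    axis-aligned ellipsoid are recovered to numerical tolerance.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise FitError("expected an (n, 3) array of points")
    if p.shape[0] < 9:
        raise FitError(f"ellipsoid fit needs at least 9 points, got {p.shape[0]}")
    x, y, z = p[:, 0], p[:, 1], p[:, 2]
    design = np.column_stack([x * x, y * y, z * z, 2 * x, 2 * y, 2 * z])
    coef, _, rank, _ = np.linalg.lstsq(design, np.ones(p.shape[0]), rcond=None)
    if rank < 6:
        raise FitError("degenerate point configuration: fit is underdetermined")
    A, B, C, D, E, F = coef
    if A <= 0 or B <= 0 or C <= 0:
        raise FitError("fitted quadric is not an ellipsoid (non-positive axis coefficient)")
    centre = (-D / A, -E / B, -F / C)
    gamma = 1.0 + D * D / A + E * E / B + F * F / C
    if gamma <= 0:
        raise FitError("fitted quadric is not an ellipsoid (imaginary radii)")
    radii = (float(np.sqrt(gamma / A)), float(np.sqrt(gamma / B)), float(np.sqrt(gamma / C)))
    return EllipsoidFit(centre=tuple(float(v) for v in centre), radii=radii)


def ellipsoid_classify(dataset: EmbryoDataset) -> tuple[EmbryoDataset, EllipsoidFit]:
    """Classify by the ellipsoid score: ν ≥ 1 ⇒ outside, ν < 1 ⇒ inside."""
    fit = fit_ellipsoid(dataset.coordinates())
    nu = fit.score(dataset.coordinates())
    classes = {
        cid: (PositionClass.OUTSIDE if v >= 1.0 else PositionClass.INSIDE)
        for cid, v in zip(dataset.cell_ids, nu)
    }
    return dataset.with_classes(classes), fit


def compare_classifiers(dataset: EmbryoDataset, truth_outside: set[str]) -> tuple[int, int]:
    """Outside-count differences (hull − truth, ellipsoid − truth).

    Mirrors validation against a marker/position-based manual count of
    outside cells: each classifier's outside count minus the ground truth.
    """
    hull_ds = convex_hull_classify(dataset)
    ell_ds, _ = ellipsoid_classify(dataset)
    n_truth = len(truth_outside)
    n_hull = sum(c.position_class is PositionClass.OUTSIDE for c in hull_ds.cells)
    n_ell = sum(c.position_class is PositionClass.OUTSIDE for c in ell_ds.cells)
    return n_hull - n_truth, n_ell - n_truth
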