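"""Seeded synthetic embryos and brute-force geometric oracles.

Generators emulate the two geometries the pipeline is built around:

* ``morula`` — a compacted ball of cells: quasi-uniform points in a sphere
  with a minimum pairwise separation (nuclei cannot overlap).
* ``blastocyst`` — a trophectoderm-like shell of points on a jittered
  sphere enclosing an off-centre cavity (an empty ball pressed against
  one wall) and an ICM-like clump filling a polar cap between shell and
  cavity on the opposite side.
* ``flattened_icm`` — as ``blastocyst`` but the inside cells form a thin
  (1–2 cell) shell-adjacent disc, emulating the flattened monolayer ICM
  seen under sustained FGF4 exposure.

Ground truth is recorded geometrically, independent of the pipeline:
shell points are outside, clump points inside; shell points whose angular
position lies beyond the ICM footprint (plus half the built-in angular
gap) are mural, the rest polar. The generator leaves an empty angular
band between the ICM footprint and the mural region so the mural/polar
boundary is unambiguous — real embryos have a continuous transition
there, which the clean ground truth deliberately avoids.

The oracles are deliberately naive re-derivations used only in tests:
an O(n⁴) circumsphere-emptiness Delaunay construction, and a linear-
programming convex-combination test for hull membership.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull

from .model import CellRecord, EmbryoDataset, PositionClass, Subpopulation, Units

__all__ = [
    "GenerationError",
    "SyntheticEmbryoSpec",
    "CellTruth",
    "make_morula",
    "make_blastocyst",
    "oracle_delaunay",
    "oracle_hull_membership",
]


class GenerationError(RuntimeError):
    """Raised when a requested point packing is infeasible."""


@dataclass(frozen=True)
class CellTruth:
    """Geometric ground truth for one generated cell."""

    position_class: PositionClass
    subpopulation: Subpopulation  # mural_te / polar_te for shell cells, else none


@dataclass(frozen=True)
class SyntheticEmbryoSpec:
    """Parameters of a synthetic blastocyst-like embryo.

    Defaults describe a mid-blastocyst in μm: a 30 μm-radius shell of 32
    trophectoderm-like cells, 16 inside cells, a cavity of 0.6·R pressed
    against one pole and nuclear centres at least 6.5 μm apart.
    """

    preset: str = "blastocyst"  # morula | blastocyst | flattened_icm
    n_outside: int = 40
    n_inside: int = 24
    outer_radius: float = 30.0
    cavity_radius: float = 18.0
    cavity_centre_offset: tuple[float, float, float] | None = None  # auto: hugged against +z wall
    min_separation: float = 6.5
    seed: int = 0
    # geometry details
    icm_cap_angle: float = math.pi / 4  # half-angle of the ICM footprint cone (rad)
    mural_gap_angle: float = 0.6        # empty shell band between footprint and mural region (rad)
    radial_jitter: float = 0.04         # outward-only shell radius jitter, fraction of R
    icm_outer_frac: float = 0.82        # inside cells confined to radius ≤ frac·R
    icm_separation: float = 5.0         # min separation among/to inside cells (ICM nuclei pack tighter)

    def __post_init__(self) -> None:
        if self.preset not in ("morula", "blastocyst", "flattened_icm"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.cavity_radius >= self.outer_radius:
            raise ValueError("cavity_radius must be smaller than outer_radius")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")

    def resolved_cavity_centre(self) -> np.ndarray:
        if self.cavity_centre_offset is not None:
            return np.asarray(self.cavity_centre_offset, dtype=float)
        if self.cavity_radius == 0:
            return np.zeros(3)
        z = max(0.0, self.outer_radius - self.cavity_radius - 0.1 * self.outer_radius)
        return np.array([0.0, 0.0, z])

    def icm_axis(self) -> np.ndarray:
        """Unit vector from centre towards the ICM pole (opposite the cavity)."""
        c = self.resolved_cavity_centre()
        norm = np.linalg.norm(c)
        return -c / norm if norm > 0 else np.array([0.0, 0.0, -1.0])


_MAX_TRIES_PER_POINT = 2000


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _min_dist(p: np.ndarray, accepted: list[np.ndarray]) -> float:
    if not accepted:
        return math.inf
    return float(np.min(np.linalg.norm(np.asarray(accepted) - p, axis=1)))


def _as_dataset(
    points: list[np.ndarray], embryo_id: str, condition: str
) -> EmbryoDataset:
    cells = tuple(
        CellRecord(cell_id=f"c{i + 1}", position=tuple(float(v) for v in p))
        for i, p in enumerate(points)
    )
    return EmbryoDataset(embryo_id=embryo_id, cells=cells, units=Units.UM, condition=condition)


def make_morula(
    n: int,
    radius: float = 18.0,
    min_separation: float = 6.5,
    seed: int = 0,
    embryo_id: str = "morula",
) -> tuple[EmbryoDataset, set[str]]:
    """Quasi-uniform packed ball of ``n`` cell centres.

    Returns the dataset and the ground-truth outside set (the convex-hull
    vertices of the generated points — for a packed ball the surface cells
    are by construction the hull-generating ones). Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    points: list[np.ndarray] = []
    for _ in range(n):
        for _try in range(_MAX_TRIES_PER_POINT):
            p = rng.uniform(-radius, radius, size=3)
            if np.linalg.norm(p) > radius:
                continue
            if _min_dist(p, points) >= min_separation:
                points.append(p)
                break
        else:
            raise GenerationError(
                f"could not pack {n} points with separation {min_separation} in a ball of radius {radius}"
            )
    dataset = _as_dataset(points, embryo_id, condition="synthetic-morula")
    if n >= 5:
        hull = ConvexHull(np.asarray(points))
        truth_outside = {f"c{int(i) + 1}" for i in hull.vertices}
    else:
        truth_outside = {f"c{i + 1}" for i in range(n)}
    return dataset, truth_outside


def make_blastocyst(
    spec: SyntheticEmbryoSpec,
) -> tuple[EmbryoDataset, dict[str, CellTruth]]:
    """Generate a blastocyst-like embryo with geometric ground truth.

    Shell points are sampled on the jittered outer sphere with the
    mural/polar gap band left empty; inside points fill the ICM region
    (polar cap, outside the cavity, within ``icm_outer_frac``·R), as a
    clump for the ``blastocyst`` preset or a thin shell-adjacent disc for
    ``flattened_icm``. With ``cavity_radius == 0`` the inside points fill
    the whole interior ball and every shell cell is polar by construction.
    """
    if spec.preset == "morula":
        raise ValueError("use make_morula for the morula preset")
    last_error: GenerationError | None = None
    for attempt in range(20):  # sequential packing can jam; retry deterministically
        try:
            return _generate_blastocyst(spec, attempt)
        except GenerationError as exc:
            last_error = exc
    raise last_error


def _generate_blastocyst(
    spec: SyntheticEmbryoSpec, attempt: int
) -> tuple[EmbryoDataset, dict[str, CellTruth]]:
    rng = np.random.default_rng([spec.seed, attempt])
    R = spec.outer_radius
    sep = spec.min_separation
    cavity_c = spec.resolved_cavity_centre()
    axis = spec.icm_axis()
    has_cavity = spec.cavity_radius > 0 and spec.n_inside > 0

    # cavity growth squeezes the ICM into a tighter polar cap, so the mural
    # fraction of the shell grows with cavity size
    shrink = 1.0 - 0.45 * (spec.cavity_radius / R) ** 2 if has_cavity else 1.0
    cap = spec.icm_cap_angle * shrink
    if spec.preset == "flattened_icm":
        cap = min(math.pi / 2, 1.3 * spec.icm_cap_angle * shrink)
    band_lo, band_hi = cap, cap + spec.mural_gap_angle

    # --- shell ---
    shell: list[np.ndarray] = []
    for _ in range(spec.n_outside):
        for _try in range(_MAX_TRIES_PER_POINT):
            u = _unit_vector(rng)
            if has_cavity:
                theta = math.acos(float(np.clip(np.dot(u, axis), -1, 1)))
                if band_lo < theta < band_hi:
                    continue
            r = R * (1.0 + spec.radial_jitter * rng.uniform())
            p = r * u
            if _min_dist(p, shell) >= sep:
                shell.append(p)
                break
        else:
            raise GenerationError(
                f"could not place {spec.n_outside} shell points at separation {sep} on radius {R}"
            )

    # inside points must sit strictly below every shell hull facet, else a
    # clump cell could itself become a hull vertex where shell coverage is thin
    shell_hull = ConvexHull(np.asarray(shell)) if len(shell) >= 4 else None

    def _strictly_interior(p: np.ndarray) -> bool:
        if shell_hull is None:
            return True
        margin = np.max(shell_hull.equations[:, :3] @ p + shell_hull.equations[:, 3])
        return bool(margin <= -0.3 * sep)

    # --- inside cells ---
    inner: list[np.ndarray] = []
    sep_in = spec.icm_separation
    r_max = spec.icm_outer_frac * R
    r_min = r_max - 1.4 * sep_in if spec.preset == "flattened_icm" else 0.0
    clearance = 0.5 * sep_in

    def _inner_ok(p: np.ndarray) -> bool:
        r = float(np.linalg.norm(p))
        if not (r_min <= r <= r_max):
            return False
        if not _strictly_interior(p):
            return False
        if spec.cavity_radius > 0 and np.linalg.norm(p - cavity_c) < spec.cavity_radius + clearance:
            return False
        if has_cavity and r > 0:
            theta = math.acos(float(np.clip(np.dot(p / r, axis), -1, 1)))
            if theta > cap:
                return False
        return _min_dist(p, shell + inner) >= sep_in

    # each polar shell cell gets an ICM cell seeded beneath it, so every
    # polar cell has a true inside neighbour by construction
    if has_cavity:
        polar_shell = [
            p for p in shell
            if math.acos(float(np.clip(np.dot(p / np.linalg.norm(p), axis), -1, 1))) <= cap
        ]
        reach = 2.0 * sep_in
        for s in polar_shell:
            if len(inner) >= spec.n_inside:
                break
            u = s / np.linalg.norm(s)
            for _try in range(_MAX_TRIES_PER_POINT):
                r = rng.uniform(r_max - 1.0 * sep_in, r_max)
                tangent = rng.normal(size=3)
                tangent -= np.dot(tangent, u) * u
                tangent *= rng.uniform(0, 0.8 * sep_in) / max(np.linalg.norm(tangent), 1e-12)
                p = r * u + tangent
                if np.linalg.norm(p - s) <= 0.9 * reach and _inner_ok(p):
                    inner.append(p)
                    break
            # a failed anchor is tolerated here; the reach check below decides

    while len(inner) < spec.n_inside:
        for _try in range(_MAX_TRIES_PER_POINT):
            p = rng.uniform(-r_max, r_max, size=3)
            if _inner_ok(p):
                inner.append(p)
                break
        else:
            raise GenerationError(
                f"could not place {spec.n_inside} inside points (preset {spec.preset!r}); "
                "relax min_separation, cavity_radius or cap angle"
            )

    # construction guarantee: with a cavity, polar shell cells sit within
    # true-neighbour reach of the ICM and mural cells well beyond it, so the
    # geometric truth labels are unambiguous
    if has_cavity:
        for p in shell:
            theta = math.acos(float(np.clip(np.dot(p / np.linalg.norm(p), axis), -1, 1)))
            d_icm = _min_dist(p, inner)
            if theta <= cap and d_icm > reach:
                raise GenerationError("polar shell cell left without a nearby inside cell")
            if theta > cap and d_icm < 2.9 * sep_in:
                raise GenerationError("mural shell cell too close to the ICM clump")

    dataset = _as_dataset(shell + inner, f"{spec.preset}-s{spec.seed}", condition=f"synthetic-{spec.preset}")

    truth: dict[str, CellTruth] = {}
    mural_boundary = cap + 0.5 * spec.mural_gap_angle
    for i, p in enumerate(shell):
        cid = f"c{i + 1}"
        if spec.n_inside == 0:
            sub = Subpopulation.MURAL_TE
        elif not has_cavity:
            sub = Subpopulation.POLAR_TE
        else:
            u = p / np.linalg.norm(p)
            theta = math.acos(float(np.clip(np.dot(u, axis), -1, 1)))
            sub = Subpopulation.MURAL_TE if theta > mural_boundary else Subpopulation.POLAR_TE
        truth[cid] = CellTruth(position_class=PositionClass.OUTSIDE, subpopulation=sub)
    for j in range(len(inner)):
        truth[f"c{len(shell) + j + 1}"] = CellTruth(
            position_class=PositionClass.INSIDE, subpopulation=Subpopulation.NONE
        )
    return dataset, truth


# ---------------------------------------------------------------------------
# Brute-force oracles (test-time verification only)
# ---------------------------------------------------------------------------


def _circumsphere(p: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Centre and radius of the sphere through 4 points; None if coplanar."""
    a = 2.0 * (p[1:] - p[0])
    b = np.sum(p[1:] ** 2 - p[0] ** 2, axis=1)
    det = np.linalg.det(a)
    scale = np.prod(np.linalg.norm(a, axis=1))
    if scale == 0 or abs(det) < 1e-9 * scale:
        return None
    centre = np.linalg.solve(a, b)
    return centre, float(np.linalg.norm(p[0] - centre))


def oracle_delaunay(points: np.ndarray, rel_tol: float = 1e-9) -> set[tuple[int, int]]:
    """O(n⁴) Delaunay edge set by direct circumsphere-emptiness testing.

    A 4-subset forms a Delaunay tetrahedron iff its circumsphere contains
    no other point; the edge set is the union over all such tetrahedra.
    Intended for n ≤ 20. Near-cospherical configurations (a fifth point on
    the circumsphere within tolerance) make the tetrahedron ambiguous; the
    oracle abstains on that subset with a warning.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n > 20:
        raise ValueError(f"oracle is O(n⁴); refusing n = {n} > 20")
    edges: set[tuple[int, int]] = set()
    for subset in combinations(range(n), 4):
        sphere = _circumsphere(pts[list(subset)])
        if sphere is None:
            continue
        centre, radius = sphere
        tol = rel_tol * radius
        ok = True
        for q in range(n):
            if q in subset:
                continue
            d = float(np.linalg.norm(pts[q] - centre))
            if d < radius - tol:
                ok = False
                break
            if abs(d - radius) <= tol:
                warnings.warn(
                    f"oracle abstains: points {subset + (q,)} are cospherical within tolerance",
                    stacklevel=2,
                )
                ok = False
                break
        if ok:
            for i, j in combinations(subset, 2):
                edges.add((i, j))
    return edges


def oracle_hull_membership(points: np.ndarray, query_index: int) -> str:
    """'inside' if the query point is a convex combination of the others.

    Feasibility LP: find λ ≥ 0 with Σλᵢ pᵢ = q and Σλᵢ = 1 over all other
    points; feasible ⇒ the point is not needed to generate the hull
    ('inside', including points on facets), infeasible ⇒ 'vertex'.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    others = [i for i in range(n) if i != query_index]
    a_eq = np.vstack([pts[others].T, np.ones(len(others))])
    b_eq = np.concatenate([pts[query_index], [1.0]])
    res = linprog(c=np.zeros(len(others)), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    return "inside" if res.status == 0 else "vertex"
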