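# Methods

## Scope and data model

`iven` operates on per-embryo tables of 3D cell-centre coordinates
(nuclear centroids from any segmentation tool), in μm or pixels.
Coordinates are used as given; every derived distance and threshold is
in the input units. Each embryo needs at least 5 cells in general
position (a 3D triangulation is otherwise undefined); duplicate
coordinates are rejected at load rather than jittered, because they are
degenerate for the Delaunay triangulation and almost always indicate a
segmentation export problem.

Developmental stage is assigned from the cell count n: stage s ∈ {8,
16, 32, 64, 128} matches when |n − s| ≤ round(0.1·s), i.e. 8±1, 16±2,
32±3, 64±6, 128±13. The five windows are pairwise disjoint, so the
assignment is unambiguous; counts outside every window leave the stage
unassigned (which keeps the single pooled threshold, see below).

## Position classification

The primary classifier labels the vertices of the 3D convex hull of the
centre set as outside cells and everything enclosed as inside. Points
that fall exactly on a hull facet without being vertices are classified
inside — only hull-*generating* points count as outside. This is a
measure-zero situation for real coordinates; the rule just fixes the
tie-break. Hull vertex identification is delegated to Qhull's default
tolerances; the test suite cross-checks every classification against an
independent linear-programming membership test (a point is a non-vertex
iff it is a convex combination of the other points).

The comparison ellipsoid classifier fits the 6-parameter axis-aligned
quadric A x² + B y² + C z² + 2D x + 2E y + 2F z = 1 by linear least
squares and converts it to centre (o_x, o_y, o_z) and radii (a, b, c).
Each cell is scored ν = ((x−o_x)/a)² + ((y−o_y)/b)² + ((z−o_z)/c)², and
ν ≥ 1 classifies it outside. The fit is deliberately minimal (no cross
terms, no robust weighting, no RANSAC): it represents the simple
ellipsoid baseline the hull is meant to beat on deformed embryos, not a
state-of-the-art ellipsoid method. Fits that do not produce a real
ellipsoid (non-positive axis coefficients, imaginary radii, fewer than
9 points) raise an error rather than guessing.

## Neighbourhood graph and distance thresholds

Candidate neighbours are the edges of the 3D Delaunay triangulation
(union of the edges of all tetrahedra; scipy/Qhull backend). The number
of neighbours of a cell is its degree in this graph after correction.

The raw DT joins cells across the blastocyst cavity. The correction
removes every edge longer than a threshold T = P75 + k·IQR computed
from the embryo's own neighbour-distance distribution; k defaults to
0.5. Percentiles use linear interpolation between order statistics
(numpy's default). Other percentile conventions (e.g. MATLAB's
`prctile`) differ by small amounts on small samples, so thresholds
reproduced from other implementations may differ in the last digits.

Threshold modes:

* **single** — one pooled distribution of all edge lengths; used below
  the 32-cell stage (and when the stage is unassigned).
* **split** — separate thresholds from the 32-cell stage onwards (the
  TE stretches over the expanding cavity, so outside neighbour
  distances grow while inside ones shrink). The outside distribution is
  the lengths of outside–outside edges and the inside distribution the
  lengths of inside–inside edges. Mixed inside–outside edges enter
  *neither* distribution: in cavity geometries they include the long
  cavity-spanning connections whose removal is the whole point of the
  correction, and pooling them into a class distribution drags its P75
  into that tail until the threshold can no longer separate true from
  untrue neighbours (with realistic TE/ICM proportions roughly a third
  of edges with an inside endpoint are cavity-spanning, which inflates
  the inside threshold about threefold). When applied, outside–outside
  edges are tested against the outside threshold and every edge with at
  least one inside endpoint — including mixed pairs — against the
  inside threshold. An empty class distribution (e.g. a single inside
  cell) falls back to the pooled distribution with a warning.
* **fixed** — a user-supplied threshold applied to all edges.
* **auto** (default) — split from the 32-cell stage, single otherwise.

Edges exactly at the threshold are kept (the threshold is an inclusive
maximum). Thresholds are always computed from the *uncorrected* DT: the
correction needs the threshold, so any other ordering would be
circular. Correction never adds edges and is monotone in k (larger k ⇒
superset of edges). Cells may end up with zero neighbours; they are
kept in the graph with count 0, undefined (NaN) composition and median
distance, and are excluded from aggregates.

## Composition, subpopulations, summaries

A cell's neighbourhood composition is 100 × (neighbours of its own
class)/(neighbours). Outside cells with composition 100 are mural TE,
the remaining connected outside cells polar TE; inside cells with
composition 100 are deep ICM, the rest plain ICM. The labels are
computed for any embryo with both classes present; their biological
reading as mural/polar TE is only meaningful at blastocyst stages. The
mural share of the TE is 100 × mural/(mural + polar).

Frequency distributions of neighbour counts are normalised within the
chosen group (support = observed counts only) and averaged across
embryos bin-wise after unioning supports, with the SEM per bin; a
single-embryo average reports SEM 0 with a logged warning so plotting
code always receives a number. Per-embryo aggregates report both mean
and median neighbour counts per class, since either convention is
common. Group comparisons (e.g. control vs FGF4-treated) tabulate
per-condition medians and IQRs of the inside-cell statistics and the
deep-ICM fraction; hypothesis testing is deliberately out of scope.

Channel intensities are corrected for depth attenuation by dividing by
a nuclear reference channel (e.g. Hoechst) per cell, then scaled by the
embryo-wide maximum ratio so the brightest cell reads exactly 1.
Non-positive or missing reference intensities are an error naming the
offending cells.

## Synthetic embryos

The generator produces the geometries the pipeline is designed around,
with bit-reproducible output per (spec, seed) and a recorded geometric
ground truth that is independent of the pipeline.

* **morula** — n points quasi-uniform in a ball, rejection-sampled with
  a minimum pairwise separation (default 6.5 μm between nuclear
  centres); ground-truth outside set = hull vertices of the sample.
* **blastocyst** (default: 40 TE + 24 ICM cells ≈ a 64-cell
  mid-blastocyst, outer radius R = 30 μm, cavity radius 0.6·R pressed
  against one pole, TE separation ≥ 6.5 μm, ICM separation ≥ 5 μm —
  inside nuclei pack tighter than stretched TE ones). Shell points are
  sampled on the sphere with small outward-only radial jitter (4%); the
  ICM fills a polar cap opposite the cavity out to 0.82·R, strictly
  below every shell hull facet so the hull classification of the
  construction is exact. The footprint half-angle shrinks with cavity
  size (cap = 45°·(1 − 0.45·(r_cav/R)²)): a growing cavity squeezes the
  ICM into a tighter cap, which is what makes the mural fraction grow
  with cavity size.
* **flattened_icm** — as blastocyst but the inside cells form a 1–2
  cell-thick shell-adjacent disc over a wider cap, emulating the
  flattened monolayer ICM of sustained-FGF4 embryos.

Ground-truth mural/polar labels are angular: an empty band of 0.6 rad
is left between the ICM footprint and the mural shell region, and the
truth boundary runs through the middle of that band, so no generated
cell is ambiguous. Two further construction guarantees make the truth
labels achievable by the pipeline rather than merely plausible: every
polar shell cell gets an ICM cell anchored within 10 μm beneath it, and
every mural shell cell stays ≥ 14.5 μm from the ICM — bracketing the
inside thresholds the default geometry produces (≈ 11–13 μm).
Rejection packing that jams is retried deterministically (seeded by
(seed, attempt), up to 20 attempts) before raising a generation error.

What the generator does *not* emulate: real embryos have a continuous
polar→mural transition (no empty band), cell-size gradients,
segmentation noise and anisotropic z-resolution, and ICM/TE counts that
deviate from the nominal composition. Passing the synthetic tests
therefore demonstrates the correctness of the geometry, thresholding
and labelling machinery under clean conditions, not robustness to
segmentation artefacts. The construction guarantees also hold only in
parameter regimes near the defaults: e.g. with very few inside cells
the inside distance distribution becomes sparse and the inferred inside
threshold drifts outside the guaranteed bracket, and cavity radii
beyond ≈ 0.7·R leave too little room to pack the default ICM.

## Oracles

Two brute-force re-derivations verify the geometric core in tests and
in the acceptance script, and are never used in the pipeline itself:

* **Delaunay**: every 4-subset of points whose circumsphere contains no
  other point is a Delaunay tetrahedron; the edge set is the union over
  all such subsets. O(n⁴), restricted to n ≤ 20. Near-cospherical
  5-point configurations make the tetrahedron ambiguous; the oracle
  abstains on that subset with a warning rather than guessing.
* **Hull membership**: a point is a non-vertex iff the LP
  Σλᵢpᵢ = q, Σλᵢ = 1, λ ≥ 0 over the remaining points is feasible.

## Problem sizes and determinism

Synthetic verification uses 64-cell embryos (the smallest stage at
which every subpopulation and the split-threshold machinery are all
exercised), batches of 8–24 embryos for direction checks and sweeps,
and oracle comparisons on 50–100 random clouds of 8–40 points. All
randomness flows through explicit integer seeds; reruns are
byte-identical. The cavity-radius sweep for the mural-fraction check
uses radii 0.4–0.68·R, inside the packing-feasible regime noted above.
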