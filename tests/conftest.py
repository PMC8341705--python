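import numpy as np
import pytest

from iven import CellRecord, EmbryoDataset, SyntheticEmbryoSpec, make_blastocyst


def dataset_from_points(points, embryo_id="test"):
    cells = tuple(
        CellRecord(cell_id=f"c{i + 1}", position=tuple(float(v) for v in p))
        for i, p in enumerate(points)
    )
    return EmbryoDataset(embryo_id=embryo_id, cells=cells)


@pytest.fixture
def tetra_centroid():
    """Regular tetrahedron vertices plus their centroid (5 cells)."""
    verts = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    ) * 10.0
    points = np.vstack([verts, verts.mean(axis=0)])
    return dataset_from_points(points, "tetra")


@pytest.fixture
def blastocyst_pair():
    """Default-geometry synthetic blastocyst with its ground truth."""
    return make_blastocyst(SyntheticEmbryoSpec(seed=7))


def random_cloud(rng, n, radius=20.0):
    """n points quasi-uniform in a ball, no duplicates."""
    pts = []
    while len(pts) < n:
        p = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p) <= radius:
            pts.append(p)
    return np.asarray(pts)
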