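import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iven import (
    PositionClass,
    ThresholdMode,
    ThresholdSpec,
    convex_hull_classify,
    correct_adjacency,
    delaunay_adjacency,
    infer_threshold,
    median_neighbour_distance,
    neighbour_counts,
    oracle_delaunay,
)
from iven.neighbours import NeighbourGraph, resolve_threshold_mode
from iven.model import StageLabel

from conftest import dataset_from_points, random_cloud


def edge_index_set(graph, ids):
    lookup = {cid: i for i, cid in enumerate(ids)}
    return {tuple(sorted((lookup[a], lookup[b]))) for a, b in graph.edge_length}


class TestDelaunayAdjacency:
    def test_tetrahedron_centroid_has_four_neighbours(self, tetra_centroid):
        graph = delaunay_adjacency(tetra_centroid)
        assert graph.degree()["c5"] == 4
        # matches the brute-force circumsphere construction exactly
        oracle = oracle_delaunay(tetra_centroid.coordinates())
        assert edge_index_set(graph, tetra_centroid.cell_ids) == oracle

    def test_five_random_points_have_nine_or_ten_edges(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            pts = random_cloud(rng, 5)
            graph = delaunay_adjacency(dataset_from_points(pts))
            assert len(graph.edge_length) in (9, 10)

    def test_matches_circumsphere_oracle_on_seeded_clouds(self):
        rng = np.random.default_rng(1234)
        for trial in range(50):
            n = int(rng.integers(8, 16))
            pts = random_cloud(rng, n)
            ds = dataset_from_points(pts)
            graph = delaunay_adjacency(ds)
            assert edge_index_set(graph, ds.cell_ids) == oracle_delaunay(pts), f"trial {trial}"

    def test_edge_lengths_are_euclidean(self, tetra_centroid):
        graph = delaunay_adjacency(tetra_centroid)
        pts = {cid: np.array(c.position) for cid, c in zip(tetra_centroid.cell_ids, tetra_centroid.cells)}
        for (a, b), d in graph.edge_length.items():
            assert d == pytest.approx(np.linalg.norm(pts[a] - pts[b]))


class TestInferThreshold:
    @staticmethod
    def graph_with_lengths(lengths):
        nodes = tuple(f"n{i}" for i in range(len(lengths) + 1))
        edges = {(f"n{i}", f"n{i + 1}"): float(d) for i, d in enumerate(lengths)}
        return NeighbourGraph(nodes=nodes, edge_length=edges)

    def test_hand_computed_percentile_example(self):
        # P75 = 6.25, IQR = 3.5 under linear interpolation, so T = 8.0
        graph = self.graph_with_lengths([1, 2, 3, 4, 5, 6, 7, 8])
        spec = infer_threshold(graph, {}, k=0.5, mode=ThresholdMode.SINGLE)
        assert spec.p75_inside == pytest.approx(6.25)
        assert spec.iqr_inside == pytest.approx(3.5)
        assert spec.t_inside == pytest.approx(8.0)

    def test_constant_distribution_gives_t_equal_d(self):
        graph = self.graph_with_lengths([4.2] * 6)
        spec = infer_threshold(graph, {}, k=0.5, mode=ThresholdMode.SINGLE)
        assert spec.t_inside == pytest.approx(4.2)

    def test_k_zero_gives_p75(self):
        graph = self.graph_with_lengths([1, 5, 2, 8, 3])
        spec = infer_threshold(graph, {}, k=0.0, mode=ThresholdMode.SINGLE)
        assert spec.t_inside == pytest.approx(np.percentile([1, 5, 2, 8, 3], 75))

    @given(
        lengths=st.lists(st.floats(0.1, 100.0), min_size=2, max_size=40),
        k1=st.floats(0.0, 2.0),
        k2=st.floats(0.0, 2.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_threshold_affine_in_k_with_slope_iqr(self, lengths, k1, k2):
        graph = self.graph_with_lengths(lengths)
        t1 = infer_threshold(graph, {}, k=k1, mode=ThresholdMode.SINGLE)
        t2 = infer_threshold(graph, {}, k=k2, mode=ThresholdMode.SINGLE)
        iqr = t1.iqr_inside
        assert t2.t_inside - t1.t_inside == pytest.approx((k2 - k1) * iqr, abs=1e-9)

    def test_split_uses_class_specific_distributions(self):
        nodes = ("o1", "o2", "o3", "i1", "i2", "i3")
        labels = {
            "o1": PositionClass.OUTSIDE, "o2": PositionClass.OUTSIDE, "o3": PositionClass.OUTSIDE,
            "i1": PositionClass.INSIDE, "i2": PositionClass.INSIDE, "i3": PositionClass.INSIDE,
        }
        edges = {
            ("o1", "o2"): 10.0, ("o2", "o3"): 10.0,   # outside-outside
            ("i1", "i2"): 2.0, ("i2", "i3"): 2.0,     # inside-inside
            ("i1", "o1"): 50.0,                        # mixed: in neither distribution
        }
        graph = NeighbourGraph(nodes=nodes, edge_length=edges)
        spec = infer_threshold(graph, labels, k=0.5, mode=ThresholdMode.SPLIT)
        assert spec.t_outside == pytest.approx(10.0)
        assert spec.t_inside == pytest.approx(2.0)

    def test_split_with_empty_class_falls_back_to_pooled(self):
        nodes = ("o1", "o2", "o3")
        labels = {n: PositionClass.OUTSIDE for n in nodes}
        graph = NeighbourGraph(nodes=nodes, edge_length={("o1", "o2"): 3.0, ("o2", "o3"): 5.0})
        with pytest.warns(UserWarning, match="falling back"):
            spec = infer_threshold(graph, labels, k=0.0, mode=ThresholdMode.SPLIT)
        assert spec.t_inside == pytest.approx(np.percentile([3.0, 5.0], 75))

    def test_fixed_mode_passes_through(self):
        graph = self.graph_with_lengths([1, 2, 3])
        spec = infer_threshold(graph, {}, k=0.5, mode=ThresholdMode.FIXED, fixed_threshold=12.5)
        assert spec.t_inside == spec.t_outside == 12.5

    @pytest.mark.parametrize(
        "stage, expected",
        [
            (StageLabel.S8, ThresholdMode.SINGLE),
            (StageLabel.S16, ThresholdMode.SINGLE),
            (StageLabel.S32, ThresholdMode.SPLIT),
            (StageLabel.S64, ThresholdMode.SPLIT),
            (StageLabel.S128, ThresholdMode.SPLIT),
            (StageLabel.UNASSIGNED, ThresholdMode.SINGLE),
        ],
    )
    def test_auto_splits_from_32_cell_stage(self, stage, expected):
        assert resolve_threshold_mode(ThresholdMode.AUTO, stage) is expected


class TestCorrectAdjacency:
    def fixed_spec(self, t_in, t_out):
        return ThresholdSpec(k=0.5, mode=ThresholdMode.FIXED, t_inside=t_in, t_outside=t_out)

    def test_infinite_threshold_is_identity(self, tetra_centroid):
        graph = delaunay_adjacency(tetra_centroid)
        labels = {cid: PositionClass.INSIDE for cid in tetra_centroid.cell_ids}
        corrected = correct_adjacency(graph, labels, self.fixed_spec(math.inf, math.inf))
        assert corrected.edge_length == graph.edge_length
        assert corrected.corrected

    def test_threshold_below_minimum_removes_all_edges(self, tetra_centroid):
        graph = delaunay_adjacency(tetra_centroid)
        labels = {cid: PositionClass.INSIDE for cid in tetra_centroid.cell_ids}
        corrected = correct_adjacency(graph, labels, self.fixed_spec(0.1, 0.1))
        assert len(corrected.edge_length) == 0
        assert all(v == 0 for v in neighbour_counts(corrected).values())
        assert set(corrected.nodes) == set(graph.nodes)

    def test_edges_at_exactly_threshold_are_kept(self):
        nodes = ("a", "b")
        graph = NeighbourGraph(nodes=nodes, edge_length={("a", "b"): 5.0})
        labels = {"a": PositionClass.INSIDE, "b": PositionClass.INSIDE}
        corrected = correct_adjacency(graph, labels, self.fixed_spec(5.0, 5.0))
        assert ("a", "b") in corrected.edge_length

    def test_mixed_pairs_use_inside_threshold(self):
        nodes = ("o1", "o2", "i1")
        graph = NeighbourGraph(
            nodes=nodes, edge_length={("o1", "o2"): 8.0, ("i1", "o1"): 8.0, ("i1", "o2"): 3.0}
        )
        labels = {"o1": PositionClass.OUTSIDE, "o2": PositionClass.OUTSIDE, "i1": PositionClass.INSIDE}
        corrected = correct_adjacency(graph, labels, self.fixed_spec(5.0, 10.0))
        assert ("o1", "o2") in corrected.edge_length          # T_outside = 10 applies
        assert ("i1", "o1") not in corrected.edge_length      # mixed: inside T = 5
        assert ("i1", "o2") in corrected.edge_length

    def test_corrected_subset_and_nested_in_k(self, blastocyst_pair):
        ds, _ = blastocyst_pair
        classified = convex_hull_classify(ds)
        graph = delaunay_adjacency(classified)
        labels = classified.classes()
        previous = None
        for k in (0.0, 0.25, 0.5, 1.0, 2.0):
            spec = infer_threshold(graph, labels, k=k, mode=ThresholdMode.SPLIT)
            corrected = correct_adjacency(graph, labels, spec)
            assert set(corrected.edge_length) <= set(graph.edge_length)
            if previous is not None:
                assert previous <= set(corrected.edge_length)
            previous = set(corrected.edge_length)

    def test_degree_sum_equals_twice_edges(self, blastocyst_pair):
        ds, _ = blastocyst_pair
        classified = convex_hull_classify(ds)
        graph = delaunay_adjacency(classified)
        labels = classified.classes()
        spec = infer_threshold(graph, labels, k=0.5, mode=ThresholdMode.SPLIT)
        corrected = correct_adjacency(graph, labels, spec)
        for g in (graph, corrected):
            assert sum(neighbour_counts(g).values()) == 2 * len(g.edge_length)

    def test_rigid_motion_preserves_degrees_and_lengths(self):
        rng = np.random.default_rng(9)
        pts = random_cloud(rng, 20)
        ds = dataset_from_points(pts)
        graph = delaunay_adjacency(ds)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = delaunay_adjacency(dataset_from_points(pts @ q.T + np.array([5.0, 6.0, 7.0])))
        assert neighbour_counts(graph) == neighbour_counts(moved)
        for e, d in graph.edge_length.items():
            assert moved.edge_length[e] == pytest.approx(d)


class TestNeighbourStatistics:
    def test_median_neighbour_distance(self):
        nodes = ("a", "b", "c", "d", "e")
        edges = {("a", "b"): 2.0, ("a", "c"): 4.0, ("a", "d"): 9.0, ("b", "c"): 4.0}
        graph = NeighbourGraph(nodes=nodes, edge_length=edges, corrected=True)
        med = median_neighbour_distance(graph)
        assert med["a"] == pytest.approx(4.0)   # odd count: {2, 4, 9}
        assert med["b"] == pytest.approx(3.0)   # even count: midpoint of {2, 4}
        assert math.isnan(med["e"])             # isolated cell

    def test_counts_on_complete_graph(self):
        nodes = ("a", "b", "c", "d")
        edges = {(x, y): 1.0 for i, x in enumerate(nodes) for y in nodes[i + 1:]}
        graph = NeighbourGraph(nodes=nodes, edge_length=edges, corrected=True)
        assert neighbour_counts(graph) == {n: 3 for n in nodes}
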