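import math

import networkx as nx
import numpy as np
import pytest

from ssetop.skeleton_scoring import (
    Cluster,
    SearchLimits,
    SkelGraph,
    bridge_gaps,
    build_skelg,
    build_skeleton_graph,
    mark_endpoints,
    merge_cliques,
    reduce_skeleton,
    remove_sse_regions,
    skeleton_edge_weight,
    w_trace,
)
from ssetop.structure_io import SkeletonGrid, Stick
from ssetop.synthetic_fixtures import make_bundle, rasterize_skeleton


def grid_from_points(points, spacing=1.0):
    pts = np.asarray(points, dtype=float)
    origin = pts.min(axis=0) - 2.0
    idx = np.round((pts - origin) / spacing).astype(int)
    occ = np.zeros(idx.max(axis=0) + 3, dtype=np.uint8)
    occ[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    return SkeletonGrid(occ, [spacing] * 3, origin)


def chain_graph(coords, anchors=None, stubs=None):
    """A path SkelGraph through the given node coordinates."""
    g = nx.Graph()
    for k, c in enumerate(coords):
        g.add_node(k, coord=np.asarray(c, dtype=float),
                   voxels=np.asarray([c], dtype=float))
    for a, b in zip(range(len(coords)), range(1, len(coords))):
        w = float(np.linalg.norm(np.asarray(coords[a]) - np.asarray(coords[b])))
        g.add_edge(a, b, weight=w)
    return SkelGraph(graph=g, anchors=anchors or {}, anchor_stubs=stubs or {})


class TestRemoveSseRegions:
    def test_empty_grid(self):
        grid = SkeletonGrid(np.zeros((3, 3, 3)), [1.0] * 3, [0.0] * 3)
        stick = Stick(1, "H", np.zeros(3), np.array([0.0, 0, 5]))
        assert remove_sse_regions(grid, [stick]).count_foreground() == 0

    def test_voxel_on_axis_removed(self):
        grid = grid_from_points([[0, 0, 2.0]])
        stick = Stick(1, "H", np.zeros(3), np.array([0.0, 0, 5]))
        assert remove_sse_regions(grid, [stick], radius=1.0).count_foreground() == 0

    def test_distant_loop_untouched(self):
        loop_pts = [[20.0, 0, z] for z in range(5)]
        grid = grid_from_points(loop_pts)
        stick = Stick(1, "H", np.zeros(3), np.array([0.0, 0, 5]))
        out = remove_sse_regions(grid, [stick], radius=2.5)
        assert out.count_foreground() == grid.count_foreground()


class TestReduceSkeleton:
    def test_single_voxel(self):
        grid = grid_from_points([[0.0, 0, 0]])
        clusters = reduce_skeleton(grid, rng_seed=0)
        assert len(clusters) == 1
        np.testing.assert_allclose(clusters[0].centroid,
                                   grid.foreground_coords()[0])

    def test_two_far_voxels_two_clusters(self):
        grid = grid_from_points([[0.0, 0, 0], [10.0, 0, 0]])
        assert len(reduce_skeleton(grid, rng_seed=1)) == 2

    def test_partition_property_over_seeds(self):
        line = [[float(x), 0, 0] for x in range(30)]
        grid = grid_from_points(line)
        counts = []
        for seed in range(20):
            clusters = reduce_skeleton(grid, rng_seed=seed)
            assert sum(len(c.voxels) for c in clusters) == 30
            counts.append(len(clusters))
        # cluster count varies with the seed but stays in a narrow band
        assert max(counts) - min(counts) <= 6
        assert all(5 <= c <= 20 for c in counts)


class TestBuildSkelg:
    def test_adjacent_clusters_linked(self):
        clusters = [
            Cluster(np.array([0.0, 0, 0]), np.array([[0.0, 0, 0]])),
            Cluster(np.array([1.0, 0, 0]), np.array([[1.0, 0, 0]])),
        ]
        sg = build_skelg(clusters)
        assert sg.graph.has_edge(0, 1)
        assert sg.graph[0][1]["weight"] == pytest.approx(1.0)

    def test_distant_clusters_not_linked(self):
        clusters = [
            Cluster(np.array([0.0, 0, 0]), np.array([[0.0, 0, 0]])),
            Cluster(np.array([10.0, 0, 0]), np.array([[10.0, 0, 0]])),
        ]
        assert build_skelg(clusters).graph.number_of_edges() == 0

    def test_chain_total_weight_near_chain_length(self):
        line = [[float(x), 0, 0] for x in range(25)]
        grid = grid_from_points(line)
        clusters = reduce_skeleton(grid, rng_seed=3)
        sg = build_skelg(clusters)
        assert nx.is_connected(sg.graph)
        total = sg.graph.size(weight="weight")
        n = sg.graph.number_of_nodes()
        assert abs(total - 24.0) <= 2.0 * n


class TestMergeCliques:
    def test_triangle_collapses(self):
        coords = [[0.0, 0, 0], [1.0, 0, 0], [0.5, 1.0, 0]]
        sg = chain_graph(coords)
        sg.graph.add_edge(0, 2, weight=1.2)  # close the triangle
        out = merge_cliques(sg)
        assert out.graph.number_of_nodes() == 1
        assert out.graph.number_of_edges() == 0

    def test_clique_free_path_unchanged(self):
        sg = chain_graph([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
        out = merge_cliques(sg)
        assert out.graph.number_of_nodes() == 3
        assert out.graph.number_of_edges() == 2

    def test_two_triangles_sharing_a_node(self):
        #  0-1-2 triangle and 2-3-4 triangle share node 2
        g = nx.Graph()
        pts = [[0, 0, 0], [2, 0, 0], [1, 1, 0], [0, 2, 0], [2, 2, 0]]
        for k, c in enumerate(pts):
            g.add_node(k, coord=np.array(c, dtype=float),
                       voxels=np.array([c], dtype=float))
        for a, b in [(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (2, 4)]:
            g.add_edge(a, b, weight=1.0)
        out = merge_cliques(SkelGraph(graph=g))
        # first triangle merges; the second loses node 2 and stays
        assert out.graph.number_of_nodes() <= 5 - 2


class TestBridgeGaps:
    def test_facing_ends_bridged(self):
        sg = chain_graph([[0.0, 0, 0], [2.0, 0, 0]])
        g2 = chain_graph([[7.0, 0, 0], [9.0, 0, 0]]).graph
        merged = nx.disjoint_union(sg.graph, g2)
        out = bridge_gaps(SkelGraph(graph=merged))
        assert nx.is_connected(out.graph)

    def test_far_ends_not_bridged(self):
        sg = chain_graph([[0.0, 0, 0], [2.0, 0, 0]])
        g2 = chain_graph([[14.1, 0, 0], [16.0, 0, 0]]).graph
        merged = nx.disjoint_union(sg.graph, g2)
        out = bridge_gaps(SkelGraph(graph=merged))
        assert not nx.is_connected(out.graph)

    def test_bridging_preserves_cheaper_existing_routes(self):
        coords = [[0.0, 0, 0], [3.0, 0, 0], [6.0, 0, 0]]
        sg = chain_graph(coords)
        before = nx.shortest_path_length(sg.graph, 0, 2, weight="weight")
        out = bridge_gaps(sg)
        after = nx.shortest_path_length(out.graph, 0, 2, weight="weight")
        assert after <= before


class TestMarkEndpoints:
    def test_single_node_anchors_everything(self):
        sg = chain_graph([[0.0, 0, 0]])
        stick = Stick(1, "H", np.array([5.0, 0, 0]), np.array([9.0, 0, 0]))
        out = mark_endpoints(sg, [stick])
        assert out.anchors == {(1, 0): 0, (1, 1): 0}

    def test_node_at_endpoint_is_anchor(self):
        sg = chain_graph([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
        stick = Stick(1, "H", np.array([0.0, 0, 0]), np.array([8.0, 0, 0]))
        out = mark_endpoints(sg, [stick])
        assert out.anchors[(1, 0)] == 0
        assert out.anchors[(1, 1)] == 2
        assert out.anchor_stubs[(1, 0)] == pytest.approx(0.0)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            mark_endpoints(SkelGraph(graph=nx.Graph()), [])


class TestWTrace:
    def anchored_path(self, coords):
        n = len(coords)
        anchors = {(1, 0): 0, (1, 1): 0, (2, 0): n - 1, (2, 1): n - 1}
        return chain_graph(coords, anchors=anchors)

    def test_exact_length_gives_zero(self):
        sg = self.anchored_path([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]])
        assert w_trace(sg, 1, 0, 2, 0, s_len=10.0) == pytest.approx(0.0)

    def test_longer_path_can_fit_better(self):
        # two routes between the anchors: direct cost 10, detour cost 20
        g = nx.Graph()
        pts = {0: [0.0, 0, 0], 1: [10.0, 0, 0], 2: [5.0, 5.0, 0]}
        for k, c in pts.items():
            g.add_node(k, coord=np.array(c), voxels=np.array([c]))
        g.add_edge(0, 1, weight=10.0)
        g.add_edge(0, 2, weight=10.0)
        g.add_edge(2, 1, weight=10.0)
        sg = SkelGraph(graph=g, anchors={(1, 0): 0, (2, 0): 1})
        assert w_trace(sg, 1, 1, 2, 0, s_len=18.0) == pytest.approx(2.0)

    def test_disconnected_anchors_infinite(self):
        g = nx.Graph()
        for k, c in enumerate([[0.0, 0, 0], [50.0, 0, 0]]):
            g.add_node(k, coord=np.array(c), voxels=np.array([c]))
        sg = SkelGraph(graph=g, anchors={(1, 0): 0, (2, 0): 1})
        assert w_trace(sg, 1, 1, 2, 0, s_len=10.0) == math.inf

    def test_far_anchor_gated(self):
        sg = self.anchored_path([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]])
        sg.anchor_stubs[(1, 0)] = 9.0  # skeleton never reaches this endpoint
        assert w_trace(sg, 1, 1, 2, 0, s_len=10.0) == math.inf

    def test_nonnegative(self):
        sg = self.anchored_path([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]])
        for s_len in (2.0, 10.0, 25.0):
            assert w_trace(sg, 1, 0, 2, 0, s_len=s_len) >= 0.0


class TestSkeletonEdgeWeight:
    @pytest.mark.parametrize(
        "w_eucl,tr,e,expected",
        [
            (5.2, math.inf, 10.0, 15.2),  # missing trace penalized
            (5.2, 0.0, 10.0, 0.0),
            (5.2, 3.0, 10.0, 3.0),
        ],
    )
    def test_min_rule(self, w_eucl, tr, e, expected):
        assert skeleton_edge_weight(w_eucl, tr, e) == pytest.approx(expected)


class TestEndToEndSkeleton:
    def test_clean_bundle_true_pairs_have_finite_traces(self):
        bundle = make_bundle(4, 0, seed=21)
        grid = rasterize_skeleton(bundle)
        sg = build_skeleton_graph(grid, bundle.sticks, rng_seed=21)
        for (i, j, t), (i2, j2, t2) in zip(bundle.truth.assignments,
                                           bundle.truth.assignments[1:]):
            s_len = (bundle.params["loop_aa"][i - 1] + 1) * 3.8
            tr = w_trace(sg, j, t, j2, t2, s_len)
            assert tr < 10.0  # finite and close to the expected span

    def test_partition_after_reduction(self):
        bundle = make_bundle(3, 0, seed=22)
        grid = rasterize_skeleton(bundle)
        loops = remove_sse_regions(grid, bundle.sticks)
        clusters = reduce_skeleton(loops, rng_seed=5)
        assert sum(len(c.voxels) for c in clusters) == loops.count_foreground()
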