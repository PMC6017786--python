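"""Skeleton-trace scoring of assignment-graph edges.

The skeleton of a cryo-EM volume is a thinned voxel model that preserves
connectivity between secondary structure elements.  A loop trace along the
skeleton between two stick endpoints is strong evidence that the two
sticks are consecutive in the chain.  This module turns the voxel skeleton
into a small weighted graph and scores each assignment-graph edge by how
well the best skeleton trace matches the expected loop span:

1. voxels near stick axes are removed, leaving loop regions only;
2. remaining voxels are clustered greedily (2 Å centroid radius) into a
   reduced centroid model;
3. centroids become nodes of an undirected graph (``SkelGraph``), linked
   when their clusters come within 3 Å of each other, with Euclidean
   centroid-distance edge weights;
4. crowded regions (maximal cliques of size >= 3, found with
   Bron-Kerbosch) are collapsed to single central nodes;
5. gaps are tolerated by bridging degree-1 nodes up to 10 Å apart;
6. each stick endpoint is anchored to its nearest node.

The trace score of an edge is ``W_trace = min over traces |path cost -
sLength|`` (∞ when no trace exists within the search limits), and the
final skeleton weight is ``W_sk = min(W_Eucl + e, W_trace)`` where the
penalty ``e`` charges pairs with no skeleton trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import SkeletonGrid, Stick
from .topology_graph import TopologyGraph, s_length

#: default greedy-clustering radius around the running centroid, Å
CLUSTER_RADIUS = 2.0
#: default cluster-linking cutoff (closest inter-cluster voxel pair), Å
LINK_CUTOFF = 3.0
#: default gap-bridging cutoff between degree-1 nodes, Å
GAP_CUTOFF = 10.0
#: default no-trace penalty e added to W_Eucl, Å (order of one loop span)
E_PENALTY = 15.0
#: default radius for clearing SSE regions off the skeleton, Å
SSE_CLEAR_RADIUS = 2.5


@dataclass(frozen=True)
class SearchLimits:
    """Bounds for the depth-first trace enumeration.

    ``cost_slack`` caps path cost at ``sLength + cost_slack``;
    ``max_nodes`` caps path length in nodes.  Both guard against path
    explosion on noisy skeletons.
    """

    cost_slack: float = 20.0
    max_nodes: int = 60
    #: a stick endpoint farther than this from its anchor node has no
    #: usable trace (the skeleton does not reach that endpoint), Å
    anchor_max_dist: float = 7.0


@dataclass
class Cluster:
    """A reduced-model cluster: running centroid plus member voxel coords."""

    centroid: np.ndarray
    voxels: np.ndarray  # (n, 3) Å


@dataclass
class SkelGraph:
    """The reduced centroid graph with stick-endpoint anchors.

    Node attributes: ``coord`` (centroid, Å) and ``voxels`` (member voxel
    coordinates).  Edge weights are centroid-centroid Euclidean distances.
    ``anchors`` maps ``(stick_index, endpoint label t)`` to a node id and
    ``anchor_stubs`` to the Euclidean distance from the stick endpoint to
    that node (the unskeletonized stub next to the stick).
    """

    graph: nx.Graph
    anchors: dict[tuple[int, int], int] = field(default_factory=dict)
    anchor_stubs: dict[tuple[int, int], float] = field(default_factory=dict)

    def coord(self, node: int) -> np.ndarray:
        return self.graph.nodes[node]["coord"]

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


def _point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    tt = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    closest = a + tt[:, None] * ab
    return np.linalg.norm(points - closest, axis=1)


def remove_sse_regions(
    grid: SkeletonGrid, sticks: Sequence[Stick], radius: float = SSE_CLEAR_RADIUS
) -> SkeletonGrid:
    """Clear foreground voxels within ``radius`` of any stick axis.

    Leaves only loop regions of the skeleton, which are what carries
    connectivity information between sticks.
    """
    idx = grid.foreground_indices()
    if len(idx) == 0 or not sticks:
        return SkeletonGrid(grid.occupancy.copy(), grid.spacing, grid.origin)
    coords = grid.origin + idx * grid.spacing
    keep = np.ones(len(idx), dtype=bool)
    for stick in sticks:
        keep &= _point_segment_distance(coords, stick.p0, stick.p1) > radius
    occ = np.zeros_like(grid.occupancy)
    kept = idx[keep]
    occ[kept[:, 0], kept[:, 1], kept[:, 2]] = 1
    return SkeletonGrid(occ, grid.spacing, grid.origin)


def reduce_skeleton(
    grid: SkeletonGrid,
    cluster_radius: float = CLUSTER_RADIUS,
    rng_seed: int = 0,
) -> list[Cluster]:
    """Greedy centroid clustering of foreground voxels into a reduced model.

    Each cluster starts at a random unassigned foreground voxel and grows
    by repeatedly absorbing the nearest unassigned voxel within
    ``cluster_radius`` of the running centroid, recomputing the centroid
    after every addition.  The seed voxel order is drawn from ``rng_seed``
    so the reduction is reproducible; the partition property (every voxel
    in exactly one cluster) holds for any seed.
    """
    coords = grid.foreground_coords()
    n = len(coords)
    if n == 0:
        return []
    rng = np.random.default_rng(rng_seed)
    tree = cKDTree(coords)
    unassigned = np.ones(n, dtype=bool)
    order = rng.permutation(n)
    clusters: list[Cluster] = []
    for seed_idx in order:
        if not unassigned[seed_idx]:
            continue
        members = [seed_idx]
        unassigned[seed_idx] = False
        centroid = coords[seed_idx].astype(float).copy()
        while True:
            near = tree.query_ball_point(centroid, cluster_radius)
            cand = [k for k in near if unassigned[k]]
            if not cand:
                break
            dists = np.linalg.norm(coords[cand] - centroid, axis=1)
            pick = cand[int(np.argmin(dists))]
            members.append(pick)
            unassigned[pick] = False
            centroid = coords[members].mean(axis=0)
        clusters.append(Cluster(centroid=centroid, voxels=coords[members].copy()))
    return clusters


def build_skelg(clusters: Sequence[Cluster], link_cutoff: float = LINK_CUTOFF) -> SkelGraph:
    """Link clusters whose voxel sets come within ``link_cutoff`` of each other.

    Edge weights are Euclidean distances between cluster centroids.
    """
    g = nx.Graph()
    for k, cl in enumerate(clusters):
        g.add_node(k, coord=np.asarray(cl.centroid, dtype=float), voxels=cl.voxels)
    if len(clusters) > 1:
        all_vox = np.vstack([cl.voxels for cl in clusters])
        owner = np.concatenate([
            np.full(len(cl.voxels), k, dtype=int) for k, cl in enumerate(clusters)
        ])
        tree = cKDTree(all_vox)
        for a, b in tree.query_pairs(link_cutoff):
            ka, kb = int(owner[a]), int(owner[b])
            if ka == kb or g.has_edge(ka, kb):
                continue
            w = float(np.linalg.norm(clusters[ka].centroid - clusters[kb].centroid))
            g.add_edge(ka, kb, weight=w)
    return SkelGraph(graph=g)


def merge_cliques(sg: SkelGraph, min_clique: int = 3) -> SkelGraph:
    """Collapse maximal cliques of size >= ``min_clique`` to single nodes.

    Cliques (crowded skeleton regions) are found with the Bron-Kerbosch
    algorithm and processed in decreasing size; nodes already absorbed by
    an earlier clique are excluded from later ones.  A merged node sits at
    the geometric center of all member-cluster voxels, and inherits every
    edge that connected its members to the outside.
    """
    g = sg.graph
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g) if len(c) >= min_clique]
    cliques.sort(key=lambda c: (-len(c), c))
    group_of: dict[int, int] = {}
    groups: list[list[int]] = []
    for clique in cliques:
        remaining = [v for v in clique if v not in group_of]
        if len(remaining) < min_clique:
            continue
        gid = len(groups)
        groups.append(remaining)
        for v in remaining:
            group_of[v] = gid
    for v in g.nodes:
        if v not in group_of:
            gid = len(groups)
            groups.append([v])
            group_of[v] = gid

    out = nx.Graph()
    for gid, members in enumerate(groups):
        voxels = np.vstack([g.nodes[v]["voxels"] for v in members])
        out.add_node(gid, coord=voxels.mean(axis=0), voxels=voxels)
    for u, v in g.edges:
        gu, gv = group_of[u], group_of[v]
        if gu == gv or out.has_edge(gu, gv):
            continue
        w = float(np.linalg.norm(out.nodes[gu]["coord"] - out.nodes[gv]["coord"]))
        out.add_edge(gu, gv, weight=w)
    anchors = {key: group_of[node] for key, node in sg.anchors.items()}
    return SkelGraph(graph=out, anchors=anchors, anchor_stubs=dict(sg.anchor_stubs))


def bridge_gaps(sg: SkelGraph, gap_cutoff: float = GAP_CUTOFF) -> SkelGraph:
    """Bridge skeleton gaps: link end nodes at most ``gap_cutoff`` apart.

    End nodes mark the open ends of gaps: isolated fragment remnants,
    degree-1 nodes, and degree-2 nodes whose two neighbors lie on the
    same side (a trace terminus whose last two clusters are chord-linked
    still ends there).  Connecting nearby end pairs restores loop traces
    broken by noise or by SSE-region removal.
    """
    g = sg.graph.copy()

    def is_end(v: int) -> bool:
        nbrs = list(g.adj[v])
        if len(nbrs) <= 1:
            return True
        if len(nbrs) == 2:
            x = g.nodes[v]["coord"]
            u0 = g.nodes[nbrs[0]]["coord"] - x
            u1 = g.nodes[nbrs[1]]["coord"] - x
            return float(u0 @ u1) > 0  # both neighbors on one side
        return False

    ends = [v for v in g.nodes if is_end(v)]
    for a_i in range(len(ends)):
        for b_i in range(a_i + 1, len(ends)):
            a, b = ends[a_i], ends[b_i]
            if g.has_edge(a, b):
                continue
            w = float(np.linalg.norm(g.nodes[a]["coord"] - g.nodes[b]["coord"]))
            if w <= gap_cutoff:
                g.add_edge(a, b, weight=w)
    return SkelGraph(graph=g, anchors=dict(sg.anchors), anchor_stubs=dict(sg.anchor_stubs))


def mark_endpoints(sg: SkelGraph, sticks: Sequence[Stick]) -> SkelGraph:
    """Anchor each stick endpoint (p0 and p1) to its nearest graph node."""
    g = sg.graph
    if g.number_of_nodes() == 0:
        raise ValueError("cannot mark stick endpoints on an empty skeleton graph")
    nodes = list(g.nodes)
    coords = np.array([g.nodes[v]["coord"] for v in nodes])
    anchors: dict[tuple[int, int], int] = {}
    stubs: dict[tuple[int, int], float] = {}
    for stick in sticks:
        for t in (0, 1):
            d = np.linalg.norm(coords - stick.endpoint(t), axis=1)
            best = int(np.argmin(d))
            anchors[(stick.stick_index, t)] = nodes[best]
            stubs[(stick.stick_index, t)] = float(d[best])
    return SkelGraph(graph=g, anchors=anchors, anchor_stubs=stubs)


def _trace_costs(
    sg: SkelGraph, src: int, dst: int, max_cost: float, max_nodes: int
) -> list[float]:
    """Costs of all simple paths src->dst within the bounds (DFS)."""
    g = sg.graph
    if src == dst:
        return [0.0]
    costs: list[float] = []
    visited = {src}

    def dfs(node: int, cost: float, depth: int) -> None:
        for nxt, attrs in g.adj[node].items():
            if nxt in visited:
                continue
            c = cost + attrs["weight"]
            if c > max_cost:
                continue
            if nxt == dst:
                costs.append(c)
                continue
            if depth + 1 >= max_nodes:
                continue
            visited.add(nxt)
            dfs(nxt, c, depth + 1)
            visited.remove(nxt)

    dfs(src, 0.0, 1)
    return costs


def w_trace(
    sg: SkelGraph,
    j: int,
    t: int,
    j2: int,
    t2: int,
    s_len: float,
    limits: SearchLimits = SearchLimits(),
) -> float:
    """Best |trace length - sLength| between two direction-aware endpoints.

    The exit anchor of ``(j, t)`` is the anchor of the endpoint the
    traversal leaves from (p1 for t=0, p0 for t=1); the entry anchor of
    ``(j2, t2)`` is the endpoint it arrives at.  A trace runs stick
    endpoint -> exit anchor -> graph path -> entry anchor -> stick
    endpoint, so the two endpoint-to-anchor stubs count toward its length;
    an endpoint farther than ``limits.anchor_max_dist`` from its anchor
    has no usable trace.  Simple paths between the anchors are enumerated
    by bounded DFS; returns ∞ when no trace exists within the limits.
    """
    src_key, dst_key = (j, 1 - t), (j2, t2)
    stub = sg.anchor_stubs.get(src_key, 0.0) + sg.anchor_stubs.get(dst_key, 0.0)
    if max(sg.anchor_stubs.get(src_key, 0.0),
           sg.anchor_stubs.get(dst_key, 0.0)) > limits.anchor_max_dist:
        return math.inf
    src = sg.anchors[src_key]
    dst = sg.anchors[dst_key]
    costs = _trace_costs(sg, src, dst, s_len - stub + limits.cost_slack, limits.max_nodes)
    if not costs:
        return math.inf
    return min(abs(c + stub - s_len) for c in costs)


def skeleton_edge_weight(w_eucl: float, w_trace_val: float, e_penalty: float = E_PENALTY) -> float:
    """Final skeleton weight: ``min(W_Eucl + e, W_trace)``.

    A missing trace (``W_trace = ∞``) falls back to the Euclidean slack
    plus the penalty ``e``.
    """
    return min(w_eucl + e_penalty, w_trace_val)


def build_skeleton_graph(
    grid: SkeletonGrid,
    sticks: Sequence[Stick],
    rng_seed: int,
    cluster_radius: float = CLUSTER_RADIUS,
    link_cutoff: float = LINK_CUTOFF,
    gap_cutoff: float = GAP_CUTOFF,
    sse_clear_radius: float = SSE_CLEAR_RADIUS,
    min_clique: int = 3,
) -> SkelGraph:
    """Full skeleton-reduction pipeline: clear SSEs, cluster, link, merge,
    bridge, anchor."""
    loops = remove_sse_regions(grid, sticks, radius=sse_clear_radius)
    clusters = reduce_skeleton(loops, cluster_radius=cluster_radius, rng_seed=rng_seed)
    sg = build_skelg(clusters, link_cutoff=link_cutoff)
    sg = merge_cliques(sg, min_clique=min_clique)
    sg = bridge_gaps(sg, gap_cutoff=gap_cutoff)
    return mark_endpoints(sg, sticks)


def score_graph_skeleton(
    g: TopologyGraph,
    sg: SkelGraph,
    e_penalty: float = E_PENALTY,
    limits: SearchLimits = SearchLimits(),
) -> None:
    """Attach ``W_sk`` to every regular edge of an assignment graph.

    Trace costs are enumerated once per anchor pair (at the largest
    sLength that pair must serve) and reused across edges.
    """
    # largest span needed per anchor pair, so one DFS serves all edges
    need: dict[tuple[int, int], float] = {}
    edge_span: dict[tuple, float] = {}
    for (u, v) in g.edges:
        (i, j, t), (i2, j2, t2) = u, v
        s_len = s_length(g.segment(i), g.segment(i2), g.chain_positions)
        edge_span[(u, v)] = s_len
        pair = (sg.anchors[(j, 1 - t)], sg.anchors[(j2, t2)])
        need[pair] = max(need.get(pair, 0.0), s_len)
    cost_cache: dict[tuple[int, int], list[float]] = {}
    for pair, s_max in need.items():
        cost_cache[pair] = _trace_costs(
            sg, pair[0], pair[1], s_max + limits.cost_slack, limits.max_nodes
        )
    for (u, v), scores in g.edges.items():
        (i, j, t), (i2, j2, t2) = u, v
        s_len = edge_span[(u, v)]
        src_key, dst_key = (j, 1 - t), (j2, t2)
        stub = sg.anchor_stubs.get(src_key, 0.0) + sg.anchor_stubs.get(dst_key, 0.0)
        if max(sg.anchor_stubs.get(src_key, 0.0),
               sg.anchor_stubs.get(dst_key, 0.0)) > limits.anchor_max_dist:
            tr = math.inf
        else:
            pair = (sg.anchors[src_key], sg.anchors[dst_key])
            costs = [c + stub for c in cost_cache[pair]
                     if c + stub <= s_len + limits.cost_slack]
            tr = min((abs(c - s_len) for c in costs), default=math.inf)
        scores.w_sk = skeleton_edge_weight(scores.w_eucl, tr, e_penalty)
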