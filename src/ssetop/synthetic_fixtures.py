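"""Desk-scale synthetic ground truth: toy bundles, skeletons, angle samples.

The generator builds the same kinds of inputs the real pipeline consumes —
a chain with backbone coordinates, SSE annotations, sticks and a voxel
skeleton — for a toy SSE bundle whose true topology is known and feasible
by construction:

* SSE axes stand roughly parallel in a row, alternating up/down, so
  consecutive elements connect with short loops near the bundle's top and
  bottom (the geometry of an antiparallel helix bundle);
* each loop is laid out as a bowed polyline whose arc length matches the
  loop-span estimate ``(loop_aa + 1) * 3.8 Å``, so a clean skeleton trace
  fits its expected span almost exactly;
* loop residue counts are drawn from a requested range but never below
  what the placed endpoint gap requires, which guarantees every
  consecutive true pair satisfies the ``vLength <= sLength`` constraint;
* stick endpoint labels (p0/p1) are flipped at random, so direction
  recovery is genuinely exercised; the flips are recorded in the true
  topology.

Skeletons are rasterized from the loop polylines onto a 1 Å grid, the
way an external skeletonizer would trace loop density, and can be
corrupted with reproducible gaps and spurs to emulate experimental noise.
Real experimental maps differ in ways the generator does not emulate:
curved SSE axes, β-sheet lateral packing, density-dependent skeleton
thickness and detector noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dp_solver import Topology
from .energy_scoring import _local_trace
from .geometry_scoring import GeometryParams
from .structure_io import (
    HELIX,
    STRAND,
    ChainModel,
    ChainResidue,
    SequenceSegment,
    SkeletonGrid,
    Stick,
    extract_sticks,
    write_chain_pdb,
    write_segments,
    write_skeleton,
    write_sticks,
)
from .topology_graph import CA_STEP

_AA = "ACDEFGHIKLMNPQRSTVWY"


class FixtureError(ValueError):
    pass


@dataclass
class FixtureBundle:
    """A complete synthetic test case with known ground truth."""

    chain: ChainModel
    segments: list[SequenceSegment]
    sticks: list[Stick]
    truth: Topology
    loops: list[np.ndarray]            # loop polylines (vertices, Å)
    axis_endpoints: dict[int, tuple[np.ndarray, np.ndarray]]  # stick -> on-axis (p0, p1)
    seed: int
    params: dict = field(default_factory=dict)


def _bowed_polyline(
    p: np.ndarray, q: np.ndarray, n_seg: int, target_len: float, normal: np.ndarray
) -> np.ndarray:
    """Polyline p->q of ``n_seg`` segments bowed out along ``normal`` until
    its arc length matches ``target_len`` (bisection to 0.05 Å)."""
    frac = np.linspace(0.0, 1.0, n_seg + 1)
    bow = np.sin(np.pi * frac)

    def verts(amp: float) -> np.ndarray:
        return p + np.outer(frac, q - p) + np.outer(amp * bow, normal)

    def length(amp: float) -> float:
        v = verts(amp)
        return float(np.linalg.norm(np.diff(v, axis=0), axis=1).sum())

    if length(0.0) >= target_len - 0.05:
        return verts(0.0)
    lo, hi = 0.0, 1.0
    while length(hi) < target_len:
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if length(mid) < target_len:
            lo = mid
        else:
            hi = mid
    return verts(0.5 * (lo + hi))


def _resample_polyline(curve: np.ndarray, n_vertices: int) -> np.ndarray:
    """Resample a polyline at ``n_vertices`` points equally spaced in arc length."""
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, cum[-1], n_vertices)
    out = np.empty((n_vertices, 3))
    for k, s in enumerate(targets):
        idx = min(int(np.searchsorted(cum, s, side="right")) - 1, len(seg) - 1)
        f = (s - cum[idx]) / seg[idx] if seg[idx] > 0 else 0.0
        out[k] = curve[idx] + f * (curve[idx + 1] - curve[idx])
    return out


def _loop_curve(
    p: np.ndarray,
    out_p: np.ndarray,
    q: np.ndarray,
    out_q: np.ndarray,
    target_len: float,
    normal: np.ndarray,
    tip_stub: float = 3.5,
) -> np.ndarray:
    """A loop path p->q that first leaves axially past the SSE tip.

    Real loops continue past the helix end before turning, so the path
    runs ``tip_stub`` Å along each SSE's outward axis direction and bows
    in between until its arc length matches ``target_len``.
    """
    p2 = p + tip_stub * out_p
    q2 = q + tip_stub * out_q
    mid_target = max(target_len - 2 * tip_stub, float(np.linalg.norm(q2 - p2)))
    mid = _bowed_polyline(p2, q2, 16, mid_target, normal)
    return np.vstack([p[None, :], mid, q[None, :]])


def make_bundle(
    n_helices: int,
    n_strands: int = 0,
    loop_len_range: tuple[int, int] = (4, 10),
    seed: int = 0,
    helix_len_range: tuple[int, int] = (14, 20),
    strand_len_range: tuple[int, int] = (8, 12),
    axis_spacing: float = 12.0,
) -> FixtureBundle:
    """Generate a toy bundle with a known, feasible true topology."""
    n_sse = n_helices + n_strands
    if n_sse < 1:
        raise FixtureError("need at least one SSE")
    lo, hi = loop_len_range
    if lo < 0 or hi < lo:
        raise FixtureError(f"bad loop length range {loop_len_range}")
    rng = np.random.default_rng(seed)

    types = [HELIX] * n_helices + [STRAND] * n_strands
    rng.shuffle(types)
    lengths = [
        int(rng.integers(*helix_len_range) if t == HELIX else rng.integers(*strand_len_range))
        for t in types
    ]

    # place SSE axes in a row, alternating up/down along z
    sse_ca: list[np.ndarray] = []       # world CA coords per SSE
    sse_axis_pts: list[np.ndarray] = [] # world on-axis point per residue
    for k, (typ, n_res) in enumerate(zip(types, lengths)):
        local_ca, _, _ = _local_trace(typ, n_res)
        local_axis = np.column_stack([
            np.zeros(n_res), np.zeros(n_res), local_ca[:, 2]
        ])
        base = np.array([
            k * axis_spacing + rng.uniform(-1.0, 1.0),
            rng.uniform(-1.5, 1.5),
            0.0,
        ])
        if k % 2 == 0:  # up
            ca_w = base + local_ca
            ax_w = base + local_axis
        else:  # down: rotate 180 deg about x, shift so the axis spans [0, L]
            flip = np.array([1.0, -1.0, -1.0])
            top = local_ca[-1, 2]
            ca_w = base + local_ca * flip + np.array([0.0, 0.0, top])
            ax_w = base + local_axis * flip + np.array([0.0, 0.0, top])
        sse_ca.append(ca_w)
        sse_axis_pts.append(ax_w)

    # end-triangle centroids: the stick endpoints the pipeline will derive
    tri0 = [ca[:3].mean(axis=0) for ca in sse_ca]
    tri1 = [ca[-3:].mean(axis=0) for ca in sse_ca]

    # outward axis directions at the SSE ends the loops leave from / enter
    def _unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    out_end = [_unit(tri1[k] - tri0[k]) for k in range(n_sse)]
    out_start = [_unit(tri0[k] - tri1[k]) for k in range(n_sse)]

    # loop lengths: drawn from the range but never below what the routed
    # path requires, kept moderate (at most 3 residues of slack) so loops
    # bow gently, and pairwise distinct so each loop's trace length is
    # unambiguous evidence for its own SSE pair
    tip_stub = 3.5
    loop_aa: list[int] = []
    for k in range(n_sse - 1):
        p, q = tri1[k], tri0[k + 1]
        p2 = p + tip_stub * out_end[k]
        q2 = q + tip_stub * out_start[k + 1]
        path_floor = 2 * tip_stub + float(np.linalg.norm(q2 - p2))
        min_aa = max(0, math.ceil((path_floor + 0.2) / CA_STEP - 1))
        if min_aa > hi:
            raise FixtureError(
                f"loop {k} needs >= {min_aa} residues but loop_len_range caps at {hi}"
            )
        lo_eff = max(lo, min_aa)
        hi_eff = max(lo_eff, min(hi, min_aa + 3))
        la = int(rng.integers(lo_eff, hi_eff + 1))
        while any(abs(la - other) < 2 for other in loop_aa):
            la += 1
        loop_aa.append(la)

    # loop paths routed past the SSE tips, arc length = loop-span estimate;
    # the fine curve is kept for rasterization, and loop CA positions are
    # resampled from it at ~3.8 Å arc spacing
    loops: list[np.ndarray] = []
    ca_paths: list[np.ndarray] = []
    for k, la in enumerate(loop_aa):
        p, q = tri1[k], tri0[k + 1]
        d = _unit(q - p)
        # bow out of the bundle plane (the axes stand in the xz plane), so
        # slack loops protrude clear of the other SSEs
        ref = rng.choice([-1.0, 1.0]) * np.array([0.0, 1.0, 0.0])
        ref = ref + 0.2 * rng.normal(size=3)
        normal = _unit(ref - (ref @ d) * d)
        curve = _loop_curve(p, out_end[k], q, out_start[k + 1],
                            (la + 1) * CA_STEP, normal, tip_stub)
        loops.append(curve)
        ca_paths.append(_resample_polyline(curve, la + 2))

    # assemble the chain: SSE residues + loop residues, contiguous numbering
    residues: list[ChainResidue] = []
    segments: list[SequenceSegment] = []
    annotation: list[tuple[str, int, int]] = []
    idx = 0

    def add_residue(ca: np.ndarray, tangent: np.ndarray) -> None:
        nonlocal idx
        idx += 1
        tn = tangent / (np.linalg.norm(tangent) + 1e-12)
        residues.append(ChainResidue(
            index=idx,
            aa=str(rng.choice(list(_AA))),
            ca=ca,
            n=ca - 0.65 * tn,
            c=ca + 0.55 * tn,
        ))

    for k in range(n_sse):
        first = idx + 1
        ca = sse_ca[k]
        for r in range(len(ca)):
            nxt = ca[min(r + 1, len(ca) - 1)] - ca[max(r - 1, 0)]
            add_residue(ca[r], nxt)
        segments.append(SequenceSegment(k + 1, types[k], first, idx))
        annotation.append((types[k], first, idx))
        if k < n_sse - 1:
            path = ca_paths[k]
            interior = path[1:-1]
            for r in range(len(interior)):
                nxt = path[min(r + 2, len(path) - 1)] - path[r]
                add_residue(interior[r], nxt)

    chain = ChainModel(chain_id="A", residues=residues)
    sticks = extract_sticks(chain, segments)

    # map each segment to its stick index (helices renumbered first)
    helix_orders = [s.order_index for s in segments if s.sse_type == HELIX]
    strand_orders = [s.order_index for s in segments if s.sse_type == STRAND]
    stick_of_segment = {
        order: j + 1 for j, order in enumerate(helix_orders + strand_orders)
    }

    # on-axis endpoints (inset to the end-triangle centroid level)
    axis_endpoints: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k in range(n_sse):
        j = stick_of_segment[k + 1]
        ax = sse_axis_pts[k]
        axis_endpoints[j] = (ax[:3].mean(axis=0), ax[-3:].mean(axis=0))

    # random endpoint-label flips: truth direction becomes t=1 where flipped
    truth_nodes: list[tuple[int, int, int]] = []
    flipped: dict[int, Stick] = {}
    for seg in segments:
        j = stick_of_segment[seg.order_index]
        stick = next(s for s in sticks if s.stick_index == j)
        if rng.random() < 0.5:
            flipped[j] = Stick(j, stick.sse_type, stick.p1.copy(), stick.p0.copy())
            a, b = axis_endpoints[j]
            axis_endpoints[j] = (b, a)
            t = 1
        else:
            flipped[j] = stick
            t = 0
        truth_nodes.append((seg.order_index, j, t))
    sticks = [flipped[s.stick_index] for s in sticks]

    truth = Topology(assignments=tuple(truth_nodes), total_score=0.0)
    return FixtureBundle(
        chain=chain,
        segments=segments,
        sticks=sticks,
        truth=truth,
        loops=loops,
        axis_endpoints=axis_endpoints,
        seed=seed,
        params=dict(
            n_helices=n_helices, n_strands=n_strands,
            loop_len_range=loop_len_range, loop_aa=loop_aa,
            helix_len_range=helix_len_range, strand_len_range=strand_len_range,
            axis_spacing=axis_spacing,
        ),
    )


def rasterize_skeleton(
    bundle: FixtureBundle, spacing: float = 1.0, include_sse: bool = False
) -> SkeletonGrid:
    """Voxelize the bundle's loop polylines onto a regular grid.

    Emulates an external skeletonizer's loop trace.  ``include_sse`` also
    rasterizes the stick axes (they are normally cleared again by the SSE
    removal step).
    """
    polylines = list(bundle.loops)
    if include_sse:
        polylines += [np.vstack([s.p0, s.p1]) for s in bundle.sticks]
    if not polylines:
        origin = np.zeros(3)
        return SkeletonGrid(np.zeros((1, 1, 1), dtype=np.uint8),
                            np.full(3, spacing), origin)
    pts = np.vstack(polylines)
    margin = 3.0
    origin = np.floor((pts.min(axis=0) - margin) / spacing) * spacing
    dims = np.ceil((pts.max(axis=0) + margin - origin) / spacing).astype(int) + 1
    occ = np.zeros(tuple(dims), dtype=np.uint8)
    for poly in polylines:
        for a, b in zip(poly, poly[1:]):
            seg_len = float(np.linalg.norm(b - a))
            n_samp = max(2, int(math.ceil(seg_len / (0.4 * spacing))) + 1)
            for f in np.linspace(0.0, 1.0, n_samp):
                p = a + f * (b - a)
                ix, iy, iz = np.round((p - origin) / spacing).astype(int)
                occ[ix, iy, iz] = 1
    return SkeletonGrid(occ, np.full(3, spacing), origin)


def corrupt_skeleton(
    grid: SkeletonGrid,
    gap_count: int,
    gap_len: float,
    spur_count: int = 0,
    seed: int = 0,
    spur_len: float = 5.0,
    protect: Sequence[np.ndarray] = (),
    protect_radius: float = 6.0,
) -> SkeletonGrid:
    """Inject gaps and spurs into a skeleton, reproducibly.

    Each gap clears all foreground voxels within ``gap_len / 2`` of a
    randomly chosen foreground voxel, leaving facing ends roughly
    ``gap_len`` apart; each spur appends a short straight run of voxels in
    a random direction.  Gap centers avoid the ``protect`` points (e.g.
    stick endpoints, so a gap interrupts a trace rather than detaching it
    from its stick).  ``gap_count = spur_count = 0`` returns an exact
    copy.
    """
    occ = grid.occupancy.copy()
    rng = np.random.default_rng(seed)
    protect_arr = np.asarray(protect, dtype=float).reshape(-1, 3)
    for _ in range(gap_count):
        idx = np.argwhere(occ > 0)
        if len(idx) == 0:
            break
        coords_all = grid.origin + idx * grid.spacing
        if len(protect_arr):
            far = np.ones(len(idx), dtype=bool)
            for p in protect_arr:
                far &= np.linalg.norm(coords_all - p, axis=1) > protect_radius + gap_len / 2
            if far.any():
                idx = idx[far]
        center = (grid.origin + idx[rng.integers(len(idx))] * grid.spacing)
        coords = grid.origin + idx * grid.spacing
        # the cluster centroids at the cut ends sit ~1 voxel inside the
        # surviving trace, so shrink the cleared ball accordingly: the
        # node-level gap the bridge rule sees then comes out near gap_len
        radius = max(float(grid.spacing.max()), gap_len / 2.0 - 1.0)
        hit = np.linalg.norm(coords - center, axis=1) <= radius
        occ[idx[hit, 0], idx[hit, 1], idx[hit, 2]] = 0
    for _ in range(spur_count):
        idx = np.argwhere(occ > 0)
        if len(idx) == 0:
            break
        start = grid.origin + idx[rng.integers(len(idx))] * grid.spacing
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        step = float(grid.spacing.min())
        for s in np.arange(step, spur_len + step / 2, step):
            p = start + s * d
            v = np.round((p - grid.origin) / grid.spacing).astype(int)
            if np.all(v >= 0) and np.all(v < occ.shape):
                occ[v[0], v[1], v[2]] = 1
    return SkeletonGrid(occ, grid.spacing.copy(), grid.origin.copy())


def sample_angles(params: GeometryParams, n: int, seed: int = 0) -> np.ndarray:
    """I.i.d. (φ, η) draws from the bivariate normal with the given Λ, Σ."""
    if n < 1:
        raise FixtureError("need n >= 1")
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(params.mean, params.cov, size=n)


def write_bundle(bundle: FixtureBundle, outdir: str | Path, spacing: float = 1.0) -> dict:
    """Write a bundle in the formats the pipeline reads; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = [(s.sse_type, s.first_res, s.last_res) for s in bundle.segments]
    paths = {
        "pdb": outdir / "bundle.pdb",
        "segments": outdir / "segments.tsv",
        "sticks": outdir / "sticks.tsv",
        "skeleton": outdir / "skeleton.mrc",
        "truth": outdir / "truth.tsv",
    }
    write_chain_pdb(bundle.chain, paths["pdb"], annotation)
    write_segments(bundle.segments, paths["segments"])
    write_sticks(bundle.sticks, paths["sticks"])
    write_skeleton(rasterize_skeleton(bundle, spacing=spacing), paths["skeleton"])
    lines = ["# truth\ti\tj\tt"] + [
        f"{i}\t{j}\t{t}" for i, j, t in bundle.truth.assignments
    ]
    paths["truth"].write_text("\n".join(lines) + "\n")
    return {k: str(v) for k, v in paths.items()}
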