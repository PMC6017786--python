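"""Pairwise multi-well contact energy between modelled SSE sticks.

Before any backbone exists, each graph node ``(i, j, t)`` is given a
simplified ideal-geometry model: a CA trace generated from ideal helix
parameters (1.5 Å rise, 100° twist per residue, 2.3 Å radius) or an ideal
extended-strand zigzag (3.3 Å axial rise, lateral pleat sized so that
consecutive CA atoms sit 3.8 Å apart), rigidly placed on the stick axis in
the node's direction.  A side-chain center is attached to every residue
along the local outward normal at a residue-type-specific distance — a
centroid approximation standing in for full rotamer packing.

Two residues are *in contact* when their side-chain centers lie within a
type-dependent cutoff.  Each contact contributes a multi-well potential: a
short-range power-law repulsion plus a set of attractive Gaussian wells,

    E(r) = (r_rep / r)^12 − Σ_k d_k · exp(−(r − r_k)² / (2 σ_k²)).

The edge energy ``W_e`` sums contact energies between the two models
(inter) and within each model (intra); pairs with no inter-model contact
fall back to a constant ``e``.  Native-like packings give negative W_e.
The cutoffs and well parameters are configuration with physically
plausible defaults (6.5 Å cutoff for all pairs; one well at 5.5 Å of depth
1 and width 1; 3.5 Å repulsion scale).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import HELIX, ChainModel, SequenceSegment, Stick
from .topology_graph import Node, TopologyGraph

logger = logging.getLogger("ssetop")

#: approximate distance from CA to the side-chain centroid, Å, per residue type
SIDE_CHAIN_DIST = {
    "G": 0.0, "A": 1.5, "S": 1.9, "C": 2.1, "P": 1.9, "T": 1.9, "V": 2.0,
    "N": 2.5, "D": 2.5, "I": 2.3, "L": 2.6, "M": 2.9, "Q": 3.0, "E": 3.0,
    "H": 3.1, "K": 3.5, "F": 3.4, "R": 4.1, "Y": 3.8, "W": 3.9,
}

HELIX_RISE = 1.5      # Å per residue along the helix axis
HELIX_TWIST = 100.0   # degrees per residue
HELIX_RADIUS = 2.3    # Å, CA distance from the axis
STRAND_RISE = 3.3     # Å per residue along the strand axis
CA_CA = 3.8           # Å, consecutive CA distance
#: lateral pleat amplitude making strand CA-CA distances come out at 3.8 Å
STRAND_PLEAT = math.sqrt(CA_CA ** 2 - STRAND_RISE ** 2) / 2.0


class EnergyError(ValueError):
    pass


@dataclass
class EnergyParams:
    """Contact cutoffs, Gaussian wells and the no-contact constant."""

    default_cutoff: float = 6.5
    pair_cutoffs: dict[frozenset, float] = field(default_factory=dict)
    wells: tuple[tuple[float, float, float], ...] = ((5.5, 1.0, 1.0),)  # (r_k, d_k, sigma_k)
    repulsion_scale: float = 3.5
    e_const: float = 0.0
    #: intra-model contacts skip residue pairs closer than this in sequence
    intra_min_separation: int = 2

    def __post_init__(self) -> None:
        if self.default_cutoff <= 0 or any(c <= 0 for c in self.pair_cutoffs.values()):
            raise EnergyError("contact cutoffs must be positive")
        if any(s <= 0 for _, _, s in self.wells):
            raise EnergyError("well widths must be positive")

    def cutoff(self, type_a: str, type_b: str) -> float:
        for t in (type_a, type_b):
            if t not in SIDE_CHAIN_DIST:
                raise EnergyError(f"unknown residue type {t!r}")
        return self.pair_cutoffs.get(frozenset((type_a, type_b)), self.default_cutoff)


@dataclass
class SseModel:
    """Ideal-geometry model of one assignment node: CA trace + side-chain
    centers, in stick coordinates."""

    sequence: str
    ca: np.ndarray          # (n, 3)
    side_chain: np.ndarray  # (n, 3)
    direction: int
    node: Node | None = None

    def __len__(self) -> int:
        return len(self.sequence)


def _local_trace(sse_type: str, n: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Ideal CA trace and outward side-chain normals along the local z axis.

    Returns (ca, normals, axial length).
    """
    k = np.arange(n)
    if sse_type == HELIX:
        ang = np.radians(HELIX_TWIST * k)
        ca = np.column_stack([
            HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), HELIX_RISE * k,
        ])
        normals = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n)])
        length = HELIX_RISE * max(n - 1, 1)
    else:
        sign = (-1.0) ** k
        ca = np.column_stack([
            STRAND_PLEAT * sign, np.zeros(n), STRAND_RISE * k,
        ])
        normals = np.column_stack([sign, np.zeros(n), np.zeros(n)])
        length = STRAND_RISE * max(n - 1, 1)
    return ca, normals, length


def _frame_for_axis(axis: np.ndarray) -> np.ndarray:
    """A deterministic rotation taking local z onto ``axis`` (unit)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    s = np.linalg.norm(v)
    c = float(z @ axis)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)


def build_sse_model(
    stick: Stick,
    segment: SequenceSegment,
    t: int,
    sequence: str | None = None,
    max_axial_scaling: float = 0.2,
) -> SseModel:
    """Build the ideal-geometry model of node (segment, stick, t).

    The ideal CA trace is rigidly aligned so its axis runs from the
    stick's entry endpoint to its exit endpoint (direction ``t``), with
    axial scaling clamped to ±``max_axial_scaling`` (a warning is logged
    when the stick and segment lengths disagree more than that).
    ``sequence`` supplies residue types for side-chain placement and
    defaults to poly-alanine.
    """
    if stick.sse_type != segment.sse_type:
        raise EnergyError("segment and stick types differ")
    n = segment.length_aa
    seq = sequence if sequence is not None else "A" * n
    if len(seq) != n:
        raise EnergyError(f"sequence length {len(seq)} != segment length {n}")
    start = stick.endpoint(t)
    end = stick.endpoint(1 - t)
    if n == 1:
        mid = (start + end) / 2.0
        return SseModel(seq, mid[None, :], mid[None, :].copy(), t)
    ca, normals, length = _local_trace(segment.sse_type, n)
    scale = stick.length / length
    clamped = float(np.clip(scale, 1 - max_axial_scaling, 1 + max_axial_scaling))
    if clamped != scale:
        logger.warning(
            "stick %d/segment %d axial scale %.2f clamped to %.2f",
            stick.stick_index, segment.order_index, scale, clamped,
        )
    ca = ca * np.array([1.0, 1.0, clamped])
    axis = (end - start) / np.linalg.norm(end - start)
    rot = _frame_for_axis(axis)
    ca_w = start + ca @ rot.T
    normals_w = normals @ rot.T
    dists = np.array([SIDE_CHAIN_DIST.get(a, 2.5) for a in seq])
    sc_w = ca_w + normals_w * dists[:, None]
    return SseModel(seq, ca_w, sc_w, t)


def in_contact(
    aa_a: str, center_a: np.ndarray, aa_b: str, center_b: np.ndarray, params: EnergyParams
) -> bool:
    """True iff the side-chain centers are within the pair's cutoff (<=)."""
    return float(np.linalg.norm(center_a - center_b)) <= params.cutoff(aa_a, aa_b)


def multiwell_energy(r: float, type_a: str, type_b: str, params: EnergyParams) -> float:
    """Short-range repulsion plus Gaussian wells, symmetric in the pair."""
    if r <= 0:
        raise EnergyError("distance must be positive")
    params.cutoff(type_a, type_b)  # validates residue types
    e = (params.repulsion_scale / r) ** 12
    for r_k, d_k, s_k in params.wells:
        e -= d_k * math.exp(-((r - r_k) ** 2) / (2 * s_k ** 2))
    return e


def pair_energy(
    m1: SseModel, m2: SseModel, params: EnergyParams | None = None
) -> tuple[float, bool]:
    """(W_e, has_contacts) for two SSE models.

    W_e sums the multi-well energy over inter-model contact pairs and over
    intra-model contact pairs of both models (sequence-adjacent residues
    are excluded from the intra term); ``has_contacts`` reports whether
    the two models touch at all.
    """
    params = params or EnergyParams()
    total = 0.0
    has_contacts = False
    max_cut = max([params.default_cutoff, *params.pair_cutoffs.values()]
                  if params.pair_cutoffs else [params.default_cutoff])
    tree2 = cKDTree(m2.side_chain)
    for a, (aa_a, ca) in enumerate(zip(m1.sequence, m1.side_chain)):
        for b in tree2.query_ball_point(ca, max_cut):
            aa_b = m2.sequence[b]
            r = float(np.linalg.norm(ca - m2.side_chain[b]))
            if r <= params.cutoff(aa_a, aa_b):
                has_contacts = True
                total += multiwell_energy(r, aa_a, aa_b, params)
    for m in (m1, m2):
        for a in range(len(m)):
            for b in range(a + params.intra_min_separation, len(m)):
                r = float(np.linalg.norm(m.side_chain[a] - m.side_chain[b]))
                if r <= params.cutoff(m.sequence[a], m.sequence[b]):
                    total += multiwell_energy(r, m.sequence[a], m.sequence[b], params)
    return total, has_contacts


def energy_edge_weight(w_e: float, has_contacts: bool, e_const: float = 0.0) -> float:
    """``W_e`` when the two SSEs are in contact, the constant ``e`` otherwise."""
    return w_e if has_contacts else e_const


def score_graph_energy(
    g: TopologyGraph,
    chain: ChainModel | None = None,
    params: EnergyParams | None = None,
) -> None:
    """Attach the energy weight to every regular edge of the graph.

    Models are built once per node and reused; segment sequences come from
    the chain when available, otherwise poly-alanine.
    """
    params = params or EnergyParams()

    def seq_of(segment: SequenceSegment) -> str | None:
        if chain is None:
            return None
        a = chain.position(segment.first_res)
        b = chain.position(segment.last_res)
        return "".join(chain.residues[k].aa for k in range(a, b + 1))

    models: dict[Node, SseModel] = {}

    def model(node: Node) -> SseModel:
        if node not in models:
            i, j, t = node
            seg = g.segment(i)
            models[node] = build_sse_model(g.stick(j), seg, t, sequence=seq_of(seg))
        return models[node]

    for (u, v), scores in g.edges.items():
        w_e, touching = pair_energy(model(u), model(v), params)
        scores.has_contacts = touching
        scores.w_e = energy_edge_weight(w_e, touching, params.e_const)
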