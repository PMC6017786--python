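"""The weighted layered assignment graph over (segment, stick, direction) nodes.

Topology determination asks which volume stick each sequence SSE occupies,
and in which direction.  The search space is organised as a directed
layered graph: a regular node ``(i, j, t)`` assigns sequence segment
``SQ_i`` to stick ``D_j`` traversed in direction ``t`` (t=0 runs p0->p1,
t=1 the reverse).  Two special nodes START and END frame complete
assignments.  Helix segments pair only with helix sticks and strands only
with strand sticks, so the graph has at most ``2*M_H*N_H + 2*M_b*N_b``
regular nodes.

An edge from ``(i,j,t)`` to ``(i',j',t')`` (``i' > i``, ``j' != j``) is
emitted only when the loop between the two segments can physically bridge
the gap between the corresponding stick endpoints:

    sLength(i,i') = (Loop#aa(i,i') + 1) * 3.8 Å      (CA-CA step length)
    vLength       = |exit endpoint of (j,t) - entry endpoint of (j',t')|

The edge exists iff ``vLength <= sLength`` and carries the base weight
``W_Eucl = sLength - vLength`` (slack of the loop).  Rows may be skipped
(segments left unassigned) up to ``max_skip`` consecutive rows, bounded by
``Δ - 1`` where ``Δ = M - N + 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .structure_io import HELIX, STRAND, SequenceSegment, Stick, StructureError

#: spatial distance between consecutive CA atoms in protein structures, Å
CA_STEP = 3.8

Node = tuple[int, int, int]  # (i, j, t)


class GraphError(ValueError):
    """Raised for invalid graph construction requests."""


@dataclass
class EdgeScores:
    """Per-edge score components; ``weight`` is the active scheme weight."""

    w_eucl: float
    w_sk: float | None = None
    f_geom: float | None = None
    w_e: float | None = None
    has_contacts: bool = False
    weight: float = 0.0

    def __post_init__(self) -> None:
        self.weight = self.w_eucl


def _loop_aa(
    seg_a: SequenceSegment,
    seg_b: SequenceSegment,
    chain_positions: Mapping[int, int] | None,
) -> int:
    """Residues strictly between two segments, by sequential chain position.

    Residues belonging to any skipped intervening segment count as loop
    residues.  Without a chain, author numbering is assumed contiguous.
    """
    if chain_positions is None:
        return seg_b.first_res - seg_a.last_res - 1
    return chain_positions[seg_b.first_res] - chain_positions[seg_a.last_res] - 1


def s_length(
    seg_a: SequenceSegment,
    seg_b: SequenceSegment,
    chain_positions: Mapping[int, int] | None = None,
) -> float:
    """Estimated maximum span of the loop between two segments, in Å.

    ``sLength = (Loop#aa + 1) * 3.8`` — the fully extended length of the
    connecting loop.
    """
    if seg_b.order_index <= seg_a.order_index:
        raise GraphError("second segment must come after the first in sequence")
    n_loop = _loop_aa(seg_a, seg_b, chain_positions)
    if n_loop < 0:
        raise GraphError("segments overlap or are out of order")
    return (n_loop + 1) * CA_STEP


def v_length(stick_a: Stick, t_a: int, stick_b: Stick, t_b: int) -> float:
    """Euclidean distance from the exit end of (j,t) to the entry end of (j',t').

    Direction t=0 runs p0->p1, so its exit endpoint is p1 and the entry
    endpoint of the next stick is its p0; t=1 swaps both.
    """
    if stick_a.stick_index == stick_b.stick_index:
        raise GraphError("v_length needs two distinct sticks")
    exit_pt = stick_a.endpoint(1 - t_a)
    entry_pt = stick_b.endpoint(t_b)
    return float(np.linalg.norm(entry_pt - exit_pt))


def w_eucl(
    seg_a: SequenceSegment,
    seg_b: SequenceSegment,
    stick_a: Stick,
    t_a: int,
    stick_b: Stick,
    t_b: int,
    chain_positions: Mapping[int, int] | None = None,
) -> float:
    """Base edge weight ``sLength - vLength`` (loop slack, >= 0 on feasible edges)."""
    return s_length(seg_a, seg_b, chain_positions) - v_length(stick_a, t_a, stick_b, t_b)


def count_topologies(m_h: int, n_h: int, m_b: int, n_b: int) -> int:
    """Number of possible topologies: C(M,N)·N!·2^N per SSE type, multiplied."""
    for m, n in ((m_h, n_h), (m_b, n_b)):
        if n < 0 or m < n:
            raise GraphError(f"need M >= N >= 0 per type, got M={m}, N={n}")
    return (
        math.comb(m_h, n_h) * math.factorial(n_h) * 2 ** n_h
        * math.comb(m_b, n_b) * math.factorial(n_b) * 2 ** n_b
    )


@dataclass
class TopologyGraph:
    """Layered assignment graph with per-edge score components."""

    segments: list[SequenceSegment]
    sticks: list[Stick]
    chain_positions: dict[int, int] | None
    max_skip: int
    nodes: set[Node] = field(default_factory=set)
    edges: dict[tuple[Node, Node], EdgeScores] = field(default_factory=dict)
    start_nodes: list[Node] = field(default_factory=list)
    end_nodes: list[Node] = field(default_factory=list)
    _adj: dict[Node, list[Node]] = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_sticks(self) -> int:
        return len(self.sticks)

    @property
    def delta(self) -> int:
        return self.n_segments - self.n_sticks + 1

    def out_neighbors(self, node: Node) -> list[Node]:
        return self._adj.get(node, [])

    def edge(self, u: Node, v: Node) -> EdgeScores:
        return self.edges[(u, v)]

    def add_edge(self, u: Node, v: Node, scores: EdgeScores) -> None:
        self.edges[(u, v)] = scores
        self._adj.setdefault(u, []).append(v)

    def segment(self, i: int) -> SequenceSegment:
        return self.segments[i - 1]

    def stick(self, j: int) -> Stick:
        return self.sticks[j - 1]

    def export_edges(self, path: str | Path) -> None:
        """Debug dump: one TSV row per edge with all score components."""
        lines = ["# src_i\tsrc_j\tsrc_t\tdst_i\tdst_j\tdst_t\tw_eucl\tw_sk\tf_geom\tw_e\tweight"]
        for (u, v), sc in sorted(self.edges.items()):
            fmt = lambda x: "" if x is None else f"{x:.4f}"
            lines.append("\t".join(map(str, (*u, *v))) + "\t"
                         + "\t".join([f"{sc.w_eucl:.4f}", fmt(sc.w_sk),
                                      fmt(sc.f_geom), fmt(sc.w_e), f"{sc.weight:.4f}"]))
        Path(path).write_text("\n".join(lines) + "\n")


def build_graph(
    segments: Sequence[SequenceSegment],
    sticks: Sequence[Stick],
    chain_positions: Mapping[int, int] | None = None,
    max_skip: int | None = None,
) -> TopologyGraph:
    """Build the layered graph with loop-span feasibility pruning.

    ``max_skip`` bounds consecutive unassigned rows and defaults to
    ``Δ - 1``; START reaches a node only if enough rows remain below it to
    place all N sticks, and symmetrically for END (a pruning optimisation,
    not a semantics change).
    """
    segments = list(segments)
    sticks = list(sticks)
    m_h = sum(1 for s in segments if s.sse_type == HELIX)
    m_b = len(segments) - m_h
    n_h = sum(1 for s in sticks if s.sse_type == HELIX)
    n_b = len(sticks) - n_h
    if m_h < n_h or m_b < n_b:
        raise GraphError(
            f"need at least as many segments as sticks per type "
            f"(helix {m_h} vs {n_h}, strand {m_b} vs {n_b})"
        )
    m_total, n_total = len(segments), len(sticks)
    delta = m_total - n_total + 1
    if max_skip is None:
        max_skip = delta - 1

    g = TopologyGraph(
        segments=segments,
        sticks=sticks,
        chain_positions=dict(chain_positions) if chain_positions is not None else None,
        max_skip=max_skip,
    )
    for seg in segments:
        for stick in sticks:
            if seg.sse_type != stick.sse_type:
                continue
            for t in (0, 1):
                g.nodes.add((seg.order_index, stick.stick_index, t))

    for i, j, t in sorted(g.nodes):
        # START may skip rows 1..i-1; END may skip rows i+1..M
        if i - 1 <= max_skip and m_total - i >= n_total - 1:
            g.start_nodes.append((i, j, t))
        if m_total - i <= max_skip and i - 1 >= n_total - 1:
            g.end_nodes.append((i, j, t))

    nodes_by_row: dict[int, list[Node]] = {}
    for node in sorted(g.nodes):
        nodes_by_row.setdefault(node[0], []).append(node)
    for i, j, t in sorted(g.nodes):
        seg_a = g.segment(i)
        stick_a = g.stick(j)
        for i2 in range(i + 1, min(i + max_skip + 1, m_total) + 1):
            seg_b = g.segment(i2)
            s_len = s_length(seg_a, seg_b, g.chain_positions)
            for (_, j2, t2) in nodes_by_row.get(i2, []):
                if j2 == j:
                    continue
                v_len = v_length(stick_a, t, g.stick(j2), t2)
                if v_len > s_len:
                    continue  # loop cannot span the gap: no edge
                g.add_edge((i, j, t), (i2, j2, t2), EdgeScores(w_eucl=s_len - v_len))
    return g
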