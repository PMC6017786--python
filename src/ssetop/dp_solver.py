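"""Shortest and best-K valid topologies on the assignment graph.

A valid topology is a START->END path that uses every stick column exactly
once, with strictly increasing segment rows.  The solver works on the
expanded state DAG with states ``(i, j, t, used-column bitmask)``: every
path through the state DAG is valid by construction, so no validity
re-checking is needed on alternative paths.  The bitmask caps the number
of sticks at 24, comfortably above the sizes the method targets.

Complexity of the single-shortest-path pass is O(Δ²·N²·2^N) in the number
of sticks N and the skip slack Δ = M - N + 1.  The best-K search keeps the
K cheapest partial paths per state, merged in topological order — a
deviation-free equivalent of Yen-style K-shortest-path search on a DAG
that also tolerates negative edge weights (which mixed scoring schemes
produce).  Ties in total score are broken lexicographically on the
``(i, j, t)`` triples, making ranks deterministic.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

from .structure_io import HELIX
from .topology_graph import GraphError, Node, TopologyGraph, count_topologies

MAX_STICKS = 24


@dataclass(frozen=True)
class Topology:
    """One complete valid assignment with its total score and rank."""

    assignments: tuple[Node, ...]
    total_score: float
    rank: int = 0

    def __str__(self) -> str:
        return ", ".join(
            f"SQ{i}→D{j}{'+' if t == 0 else '-'}" for i, j, t in self.assignments
        )

    def key(self) -> tuple[Node, ...]:
        """Identity of the topology: the ordered (i, j, t) triples."""
        return self.assignments


def _check_size(g: TopologyGraph) -> None:
    if g.n_sticks > MAX_STICKS:
        raise GraphError(
            f"solver supports at most {MAX_STICKS} sticks (bitmask state); got {g.n_sticks}"
        )


def _special_weight(g: TopologyGraph) -> float:
    # START/END hop weight; zero unless a test or scheme shifts it
    return getattr(g, "special_edge_weight", 0.0)


def k_best(g: TopologyGraph, k: int = 100) -> list[Topology]:
    """Up to ``k`` valid topologies in nondecreasing total score.

    Returns fewer than ``k`` entries when fewer valid topologies exist,
    and an empty list when the graph admits none.  Output order is
    deterministic: by (total score, lexicographic assignment).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    _check_size(g)
    n = g.n_sticks
    special = _special_weight(g)
    end_set = set(g.end_nodes)

    # state -> up to k best (cost, assignment tuple); bit b <=> stick b+1 used
    states: dict[tuple[Node, int], list[tuple[float, tuple[Node, ...]]]] = {}
    for node in g.start_nodes:
        mask = 1 << (node[1] - 1)
        states.setdefault((node, mask), []).append((special, (node,)))

    finals: list[tuple[float, tuple[Node, ...]]] = []
    # topological order: popcount strictly increases along every transition
    for popcount in range(1, n + 1):
        layer = [s for s in states if bin(s[1]).count("1") == popcount]
        for state in sorted(layer):
            node, mask = state
            entries = sorted(states[state])[:k]
            states[state] = entries
            if popcount == n:
                if node in end_set:
                    finals.extend((c + special, p) for c, p in entries)
                continue
            for nxt in g.out_neighbors(node):
                bit = 1 << (nxt[1] - 1)
                if mask & bit:
                    continue
                w = g.edge(node, nxt).weight
                tgt = states.setdefault((nxt, mask | bit), [])
                tgt.extend((c + w, p + (nxt,)) for c, p in entries)

    finals.sort()
    return [
        Topology(assignments=p, total_score=c, rank=r)
        for r, (c, p) in enumerate(finals[:k], start=1)
    ]


def shortest_valid_path(g: TopologyGraph) -> Topology | None:
    """The minimum-total-weight valid topology, or None if no topology exists."""
    best = k_best(g, 1)
    return best[0] if best else None


def enumerate_all(g: TopologyGraph, cap: int = 10 ** 6) -> list[Topology]:
    """Exhaustive DFS over all valid topologies, sorted like :func:`k_best`.

    Serves as the brute-force oracle for the DP/best-K search.  Refuses to
    run when the combinatorial topology count exceeds ``cap``.
    """
    m_h = sum(1 for s in g.segments if s.sse_type == HELIX)
    n_h = sum(1 for s in g.sticks if s.sse_type == HELIX)
    total = count_topologies(m_h, n_h, g.n_segments - m_h, g.n_sticks - n_h)
    if total > cap:
        raise GraphError(f"topology count {total} exceeds enumeration cap {cap}")
    _check_size(g)

    n = g.n_sticks
    special = _special_weight(g)
    end_set = set(g.end_nodes)
    out: list[tuple[float, tuple[Node, ...]]] = []

    def dfs(node: Node, mask: int, cost: float, path: tuple[Node, ...]) -> None:
        if len(path) == n:
            if node in end_set:
                out.append((cost + special, path))
            return
        for nxt in g.out_neighbors(node):
            bit = 1 << (nxt[1] - 1)
            if mask & bit:
                continue
            w = g.edge(node, nxt).weight
            dfs(nxt, mask | bit, cost + w, path + (nxt,))

    for node in g.start_nodes:
        dfs(node, 1 << (node[1] - 1), special, (node,))

    out.sort()
    return [
        Topology(assignments=p, total_score=c, rank=r)
        for r, (c, p) in enumerate(out, start=1)
    ]
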