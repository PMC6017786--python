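"""Scoring schemes, true-topology ranks and benchmark summary fractions.

Six edge-weighting schemes combine the three score components (skeleton
weight ``W_sk``, packing density ``f``, contact energy ``W_e``):

=========  =========================
name       edge weight
=========  =========================
sk         W_sk
sk+g       W_sk − f
sk+g+e     W_sk − f + W_e
sk+e       W_sk + W_e
g          A − f   (standalone flip)
g+e        (A − f) + W_e
=========  =========================

Smaller weights are better everywhere, so the standalone geometry schemes
use ``A − f`` rather than ``f`` (minimising ``f`` directly would favour
*implausible* packings).  A topology search succeeds on a protein when the
true topology appears within the top 100 ranked topologies; ``N/A`` marks
a failure.

A 25-protein benchmark table of true-topology ranks for all six schemes
(15 simulated volumes at 10 Å plus 10 experimental volumes) ships with
the package, so summary statistics are reproducible without any volume
data.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .dp_solver import Topology
from .topology_graph import TopologyGraph

SCHEME_NAMES = ("sk", "sk+g", "sk+g+e", "sk+e", "g", "g+e")

#: rank cap beyond which the true topology counts as not found
RANK_CAP = 100


class SchemeError(ValueError):
    pass


@dataclass(frozen=True)
class SchemeSpec:
    """One scoring scheme: which components it needs and its sign pattern."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise SchemeError(
                f"unknown scheme {self.name!r}; valid schemes: {', '.join(SCHEME_NAMES)}"
            )

    @property
    def uses_skeleton(self) -> bool:
        return "sk" in self.name.split("+")

    @property
    def uses_geometry(self) -> bool:
        return "g" in self.name.split("+")

    @property
    def uses_energy(self) -> bool:
        return "e" in self.name.split("+")


def apply_scheme(
    g: TopologyGraph, scheme: str | SchemeSpec, geometry_amplitude: float = 1.0
) -> TopologyGraph:
    """Set every regular edge's active weight according to the scheme.

    Requires the relevant components (``w_sk``, ``f_geom``, ``w_e``) to
    have been attached to every edge beforehand; a missing component
    raises an error naming the offending edge.
    """
    spec = scheme if isinstance(scheme, SchemeSpec) else SchemeSpec(scheme)
    for (u, v), sc in g.edges.items():
        if spec.uses_skeleton and sc.w_sk is None:
            raise SchemeError(f"edge {u}->{v} lacks the skeleton score")
        if spec.uses_geometry and sc.f_geom is None:
            raise SchemeError(f"edge {u}->{v} lacks the geometry score")
        if spec.uses_energy and sc.w_e is None:
            raise SchemeError(f"edge {u}->{v} lacks the energy score")
        if spec.name == "sk":
            w = sc.w_sk
        elif spec.name == "sk+g":
            w = sc.w_sk - sc.f_geom
        elif spec.name == "sk+g+e":
            w = sc.w_sk - sc.f_geom + sc.w_e
        elif spec.name == "sk+e":
            w = sc.w_sk + sc.w_e
        elif spec.name == "g":
            w = geometry_amplitude - sc.f_geom
        else:  # g+e
            w = geometry_amplitude - sc.f_geom + sc.w_e
        sc.weight = float(w)
    return g


def rank_of_truth(
    ranked: Sequence[Topology], truth: Topology, cap: int = RANK_CAP
) -> int | None:
    """1-based rank of the true topology in a sorted list, or None if it is
    absent from the top ``cap`` (a reported failure)."""
    key = truth.key()
    for pos, topo in enumerate(ranked[:cap], start=1):
        if topo.key() == key:
            return pos
    return None


def summary_fraction(table: pd.DataFrame, scheme: str, top_k: int) -> float:
    """Fraction of benchmark rows whose true-topology rank is <= ``top_k``.

    Not-found entries (``NA``) count as failures.
    """
    if scheme not in table.columns:
        raise SchemeError(f"scheme column {scheme!r} missing from table")
    ranks = pd.to_numeric(table[scheme], errors="coerce")
    return float((ranks <= top_k).sum() / len(table))


def load_benchmark_table() -> pd.DataFrame:
    """The packaged 25-protein benchmark of true-topology ranks."""
    ref = importlib.resources.files("ssetop") / "data" / "rank_benchmark.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["NA"])
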