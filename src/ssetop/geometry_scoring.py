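"""Packing-geometry scoring of consecutive SSE pairs.

Consecutive secondary structure elements pack against each other with
strongly preferred geometry.  Three vectors describe a pair: ``V1`` along
the first SSE, ``V2`` along the connecting loop (end of the first SSE to
the start of the second), ``V3`` along the second SSE.  Two angles
summarise the packing:

* ``φ`` — the signed dihedral between V1 and V3 about the loop vector V2
  (right-handed about V2, in (−180°, 180°], −180° canonicalised to +180°),
* ``η = θ1 + θ2`` — the sum of the two SSE-loop packing angles
  ``θ1 = ∠(V1, V2)`` and ``θ2 = ∠(V2, V3)``, in [0°, 360°].

Surveyed loop structures show φ and η to be approximately normal and
independent, so a pair is scored with a scaled bivariate normal density

    f(φ, η) = A · exp(−½ (x − Λ)ᵀ Σ⁻¹ (x − Λ)),   x = (φ, η)

with fitted parameters Λ = (−4.501°, 203.207°) and diagonal
Σ = diag(5581.972, 2103.773) deg².  ``A`` is a normalisation scale; the
default A = 1 keeps f in (0, 1].  Larger f means a more plausible
packing, so when f stands alone as an edge weight it is flipped to
``A − f`` (minimisation then favours probable packings); in combined
schemes f is subtracted from the skeleton weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structure_io import HELIX, ChainModel, SequenceSegment, Stick
from .topology_graph import TopologyGraph

#: fitted packing-statistics defaults: mean (deg) and covariance (deg^2)
DEFAULT_MEAN = (-4.501, 203.207)
DEFAULT_COV = ((5581.972, 0.0), (0.0, 2103.773))


class GeometryError(ValueError):
    pass


class DegenerateGeometry(GeometryError):
    """Raised when the three vectors do not define a dihedral (V2 parallel
    to V1 or V3, or a zero vector): the pair is skipped."""


@dataclass
class GeometryParams:
    """Scaled bivariate-normal parameters for (φ, η)."""

    amplitude: float = 1.0
    mean: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_MEAN))
    cov: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_COV))

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(2)
        self.cov = np.asarray(self.cov, dtype=float).reshape(2, 2)
        if not np.allclose(self.cov, self.cov.T):
            raise GeometryError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.cov) <= 0):
            raise GeometryError("covariance must be positive definite")


def _seg_anchor_points(
    chain: ChainModel, seg: SequenceSegment
) -> tuple[np.ndarray, np.ndarray] | None:
    """(start, end) anchor points of an SSE: backbone-triangle centroids of
    the first/last residue for helices, first/last CA for strands."""
    first = chain.residues[chain.position(seg.first_res)]
    last = chain.residues[chain.position(seg.last_res)]
    if seg.sse_type == HELIX:
        pts = []
        for res in (first, last):
            if res.n is None or res.c is None:
                return None  # missing backbone atoms: pair excluded
            pts.append(np.mean([res.n, res.ca, res.c], axis=0))
        return pts[0], pts[1]
    return first.ca, last.ca


def packing_vectors(
    chain: ChainModel, seg1: SequenceSegment, seg2: SequenceSegment
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """(V1, V2, V3) for a consecutive SSE pair, or None when atoms are missing.

    V1 and V3 run along the SSEs (start to end); V2 runs from the end of
    the first SSE to the start of the second.
    """
    a = _seg_anchor_points(chain, seg1)
    b = _seg_anchor_points(chain, seg2)
    if a is None or b is None:
        return None
    v1 = a[1] - a[0]
    v3 = b[1] - b[0]
    v2 = b[0] - a[1]
    return v1, v2, v3


def stick_packing_vectors(
    stick_a: Stick, t_a: int, stick_b: Stick, t_b: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(V1, V2, V3) from stick endpoints, direction-aware.

    Used when scoring graph edges, where no backbone exists yet: V1/V3 are
    the sticks oriented by their traversal direction and V2 joins the exit
    endpoint of the first to the entry endpoint of the second.
    """
    v1 = stick_a.endpoint(1 - t_a) - stick_a.endpoint(t_a)
    v3 = stick_b.endpoint(1 - t_b) - stick_b.endpoint(t_b)
    v2 = stick_b.endpoint(t_b) - stick_a.endpoint(1 - t_a)
    return v1, v2, v3


def dihedral_phi(v1: np.ndarray, v2: np.ndarray, v3: np.ndarray) -> float:
    """Signed dihedral of V1 and V3 about V2, degrees in (−180, 180].

    The angle is measured between the projections of V1 and V3 onto the
    plane perpendicular to V2, right-handed about V2; parallel SSEs give
    0° (cis) and antiparallel ones 180° (trans).
    """
    n2 = np.linalg.norm(v2)
    if n2 == 0:
        raise DegenerateGeometry("loop vector V2 is zero")
    u2 = v2 / n2
    p1 = v1 - (v1 @ u2) * u2
    p3 = v3 - (v3 @ u2) * u2
    if np.linalg.norm(p1) < 1e-9 or np.linalg.norm(p3) < 1e-9:
        raise DegenerateGeometry("SSE vector parallel to the loop vector")
    phi = math.degrees(math.atan2(float(np.cross(p1, p3) @ u2), float(p1 @ p3)))
    if phi <= -180.0:  # canonicalize -180 -> +180
        phi += 360.0
    return phi


def _angle(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateGeometry("zero vector in packing angle")
    c = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(float(c)))


def packing_eta(v1: np.ndarray, v2: np.ndarray, v3: np.ndarray) -> float:
    """Sum of the two SSE-loop packing angles, degrees in [0, 360]."""
    return _angle(v1, v2) + _angle(v2, v3)


def geometry_score(phi: float, eta: float, params: GeometryParams | None = None) -> float:
    """Scaled bivariate-normal density f(φ, η); peaks at A on the mean."""
    params = params or GeometryParams()
    x = np.array([phi, eta]) - params.mean
    det = np.linalg.det(params.cov)
    if det == 0:
        raise GeometryError("singular covariance")
    inv = np.linalg.inv(params.cov)
    return float(params.amplitude * math.exp(-0.5 * float(x @ inv @ x)))


def fit_params(samples: Sequence[tuple[float, float]], amplitude: float = 1.0) -> GeometryParams:
    """Fit Λ and a diagonal Σ from (φ, η) samples, assuming independence.

    The off-diagonal covariance is zeroed (φ and η are treated as
    independent); A sets the peak value (1 by default).
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise GeometryError("need at least 2 (phi, eta) samples")
    mean = arr.mean(axis=0)
    var = arr.var(axis=0, ddof=1)
    if np.any(var <= 0):
        raise GeometryError("degenerate sample covariance (zero variance)")
    return GeometryParams(amplitude=amplitude, mean=mean, cov=np.diag(var))


def geometry_edge_weight(
    phi: float, eta: float, params: GeometryParams | None = None, mode: str = "combined"
) -> float:
    """Edge-weight contribution of the packing score.

    ``combined`` returns f itself (to be subtracted from a skeleton
    weight); ``standalone`` returns ``A − f`` so that minimisation favours
    high-probability packings when geometry is the only score.
    """
    params = params or GeometryParams()
    f = geometry_score(phi, eta, params)
    if mode == "combined":
        return f
    if mode == "standalone":
        return params.amplitude - f
    raise GeometryError(f"unknown mode {mode!r}")


def score_graph_geometry(g: TopologyGraph, params: GeometryParams | None = None) -> None:
    """Attach the packing density f to every regular edge of the graph.

    Degenerate stick geometries (coincident endpoints, loop parallel to an
    SSE axis) carry no packing information and get f = 0.
    """
    params = params or GeometryParams()
    for (u, v), scores in g.edges.items():
        (_, j, t), (_, j2, t2) = u, v
        v1, v2, v3 = stick_packing_vectors(g.stick(j), t, g.stick(j2), t2)
        try:
            phi = dihedral_phi(v1, v2, v3)
            eta = packing_eta(v1, v2, v3)
        except DegenerateGeometry:
            scores.f_geom = 0.0
            continue
        scores.f_geom = geometry_score(phi, eta, params)
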