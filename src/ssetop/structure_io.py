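"""Structure, stick-table and skeleton-map input/output.

This module owns the four concrete representations the pipeline consumes:

* :class:`ChainModel` — one protein chain with backbone coordinates,
* :class:`SequenceSegment` — a secondary-structure element (SSE) annotated
  on the sequence (helix or strand), with its fixed sequential order,
* :class:`Stick` — an SSE detected in a cryo-EM volume, reduced to a line
  segment between two endpoints in Å,
* :class:`SkeletonGrid` — a binarized voxel skeleton of the volume.

Sticks are derived from atomic coordinates with the benchmark convention
used throughout: each endpoint is the centroid of the CA atoms of the
first (respectively last) three residues of the segment.  Helix sticks are
always listed before strand sticks, and short SSEs (helices of fewer than
six residues, strands of fewer than three) are dropped before stick
derivation, mimicking what current SSE detectors can actually find in
sub-nanometer density.

PDB structures and MRC/CCP4 maps are read and written through ``gemmi``.
The stick and segment tables are small bespoke TSV formats (there is no
community standard for "sticks"); both round-trip exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger("ssetop")

HELIX = "H"
STRAND = "E"
_TYPE_TOKENS = {"H": HELIX, "HELIX": HELIX, "E": STRAND, "STRAND": STRAND, "SHEET": STRAND}

#: minimum SSE lengths kept by :func:`extract_segments`; helices must be
#: longer than five residues and strands longer than two.
MIN_HELIX_AA = 6
MIN_STRAND_AA = 3

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1TO3 = {v: k for k, v in _AA3TO1.items()}


class StructureError(ValueError):
    """Raised for malformed or inconsistent structural inputs."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainResidue:
    """One residue of a chain: author index, 1-letter type, backbone coords."""

    index: int
    aa: str
    ca: np.ndarray
    n: np.ndarray | None = None
    c: np.ndarray | None = None


@dataclass
class ChainModel:
    """An ordered protein chain with backbone coordinates.

    Residue indices are the author residue numbers and must be strictly
    increasing; every residue carries a CA coordinate.  Loop lengths are
    computed from *sequential position* in this list, not from author
    numbering gaps.
    """

    chain_id: str
    residues: list[ChainResidue]

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StructureError("residue indices must be strictly increasing")
        self._pos = {r.index: k for k, r in enumerate(self.residues)}

    def __len__(self) -> int:
        return len(self.residues)

    def position(self, residue_index: int) -> int:
        """Sequential 0-based position of an author residue number."""
        try:
            return self._pos[residue_index]
        except KeyError:
            raise StructureError(f"residue {residue_index} not in chain {self.chain_id}") from None

    def positions(self) -> dict[int, int]:
        """Mapping author residue number -> sequential position."""
        return dict(self._pos)

    def ca(self, residue_index: int) -> np.ndarray:
        return self.residues[self.position(residue_index)].ca


@dataclass(frozen=True)
class SequenceSegment:
    """An SSE on the sequence: order index i, type, residue span."""

    order_index: int
    sse_type: str
    first_res: int
    last_res: int

    def __post_init__(self) -> None:
        if self.sse_type not in (HELIX, STRAND):
            raise StructureError(f"bad SSE type {self.sse_type!r}")
        if self.first_res > self.last_res:
            raise StructureError("segment first_res must be <= last_res")

    @property
    def length_aa(self) -> int:
        return self.last_res - self.first_res + 1


@dataclass(frozen=True)
class Stick:
    """An SSE detected in the volume: a line segment p0 -> p1 in Å.

    The two ends carry the direction labels t=0 (p0) and t=1 (p1).
    """

    stick_index: int
    sse_type: str
    p0: np.ndarray
    p1: np.ndarray

    def __post_init__(self) -> None:
        if self.sse_type not in (HELIX, STRAND):
            raise StructureError(f"bad SSE type {self.sse_type!r}")
        if np.allclose(self.p0, self.p1):
            raise StructureError(f"stick {self.stick_index} has coincident endpoints")

    def endpoint(self, t: int) -> np.ndarray:
        return self.p0 if t == 0 else self.p1

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    @property
    def axis(self) -> np.ndarray:
        v = self.p1 - self.p0
        return v / np.linalg.norm(v)


@dataclass
class SkeletonGrid:
    """A binarized voxel skeleton on an orthogonal grid.

    ``occupancy[ix,iy,iz]`` is 1 for foreground voxels; voxel centers sit
    at ``origin + index * spacing`` (Å).
    """

    occupancy: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=np.uint8)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise StructureError("voxel spacing must be positive")
        if not np.isin(self.occupancy, (0, 1)).all():
            raise StructureError("occupancy must be binary")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.occupancy.shape)  # type: ignore[return-value]

    def foreground_indices(self) -> np.ndarray:
        return np.argwhere(self.occupancy > 0)

    def foreground_coords(self) -> np.ndarray:
        """Å coordinates of all foreground voxel centers, shape (n, 3)."""
        return self.origin + self.foreground_indices() * self.spacing

    def count_foreground(self) -> int:
        return int(self.occupancy.sum())


# ---------------------------------------------------------------------------
# chains and annotations
# ---------------------------------------------------------------------------

def _residue_from_gemmi(res: gemmi.Residue) -> ChainResidue | None:
    def coord(name: str) -> np.ndarray | None:
        at = res.find_atom(name, "*")
        if at is None:
            return None
        return np.array([at.pos.x, at.pos.y, at.pos.z])

    ca = coord("CA")
    if ca is None:
        return None
    return ChainResidue(
        index=res.seqid.num,
        aa=_AA3TO1.get(res.name, "X"),
        ca=ca,
        n=coord("N"),
        c=coord("C"),
    )


def read_chain(structure_file: str | Path, chain_id: str) -> ChainModel:
    """Read one chain of a PDB file into a :class:`ChainModel`.

    Residues without a CA atom are skipped with a warning.  A missing
    chain raises an error that names the chains actually present.
    """
    st = gemmi.read_structure(str(structure_file))
    st.setup_entities()
    model = st[0]
    names = [ch.name for ch in model]
    if chain_id not in names:
        raise StructureError(
            f"chain {chain_id!r} not found in {structure_file}; available chains: {names}"
        )
    residues: list[ChainResidue] = []
    for res in model[chain_id]:
        r = _residue_from_gemmi(res)
        if r is None:
            logger.warning("residue %s %d in chain %s has no CA; skipped",
                           res.name, res.seqid.num, chain_id)
            continue
        residues.append(r)
    return ChainModel(chain_id=chain_id, residues=residues)


def read_annotation(structure_file: str | Path, chain_id: str) -> list[tuple[str, int, int]]:
    """SSE annotation (type, first_res, last_res) from PDB HELIX/SHEET records."""
    st = gemmi.read_structure(str(structure_file))
    spans: list[tuple[str, int, int]] = []
    for h in st.helices:
        if h.start.chain_name == chain_id:
            spans.append((HELIX, h.start.res_id.seqid.num, h.end.res_id.seqid.num))
    for sheet in st.sheets:
        for strand in sheet.strands:
            if strand.start.chain_name == chain_id:
                spans.append((STRAND, strand.start.res_id.seqid.num,
                              strand.end.res_id.seqid.num))
    spans.sort(key=lambda s: s[1])
    return spans


def extract_segments(
    annotation: Iterable[tuple[str, int, int]],
    min_helix_aa: int = MIN_HELIX_AA,
    min_strand_aa: int = MIN_STRAND_AA,
) -> list[SequenceSegment]:
    """Filter SSE spans by the minimum-length rule and renumber them 1..M.

    Helices shorter than ``min_helix_aa`` residues and strands shorter than
    ``min_strand_aa`` are dropped (detectors cannot find them reliably in
    sub-nanometer maps).  Survivors keep sequence order.
    """
    spans = []
    for typ, first, last in annotation:
        typ = _TYPE_TOKENS.get(str(typ).upper())
        if typ is None:
            raise StructureError(f"unknown SSE type token {typ!r}")
        if first > last:
            raise StructureError(f"span ({first},{last}) reversed")
        spans.append((typ, int(first), int(last)))
    spans.sort(key=lambda s: s[1])
    for (_, _, a_last), (_, b_first, _) in zip(spans, spans[1:]):
        if b_first <= a_last:
            raise StructureError("SSE annotation spans overlap")
    out: list[SequenceSegment] = []
    for typ, first, last in spans:
        n_aa = last - first + 1
        if typ == HELIX and n_aa < min_helix_aa:
            continue
        if typ == STRAND and n_aa < min_strand_aa:
            continue
        out.append(SequenceSegment(len(out) + 1, typ, first, last))
    return out


def extract_sticks(chain: ChainModel, segments: Sequence[SequenceSegment]) -> list[Stick]:
    """Derive volume-style sticks from a chain, one per segment.

    Each endpoint is the center of mass of the CA atoms of the segment's
    first three / last three residues (the "end triangles").  Helix sticks
    are listed before strand sticks and renumbered accordingly.
    """
    raw: list[tuple[str, np.ndarray, np.ndarray]] = []
    for seg in segments:
        a = chain.position(seg.first_res)
        b = chain.position(seg.last_res)
        n_res = b - a + 1
        if n_res < 3:
            raise StructureError(
                f"segment {seg.order_index} has {n_res} residues with CA; need >= 3"
            )
        cas = np.array([chain.residues[k].ca for k in range(a, b + 1)])
        p0 = cas[:3].mean(axis=0)
        p1 = cas[-3:].mean(axis=0)
        if np.allclose(p0, p1):
            raise StructureError(
                f"segment {seg.order_index} yields a degenerate stick (p0 == p1)"
            )
        raw.append((seg.sse_type, p0, p1))
    ordered = [r for r in raw if r[0] == HELIX] + [r for r in raw if r[0] == STRAND]
    return [Stick(k + 1, typ, p0, p1) for k, (typ, p0, p1) in enumerate(ordered)]


# ---------------------------------------------------------------------------
# skeleton maps (MRC/CCP4)
# ---------------------------------------------------------------------------

def read_skeleton(map_file: str | Path, threshold: float = 0.0) -> SkeletonGrid:
    """Read an MRC skeleton map and binarize at ``threshold``.

    A voxel with stored density strictly greater than the threshold is a
    foreground voxel.  Spacing and origin come from the map header.
    """
    m = gemmi.read_ccp4_map(str(map_file))
    grid = m.grid
    data = np.array(grid, copy=True)
    spacing = np.array([
        grid.unit_cell.a / grid.nu,
        grid.unit_cell.b / grid.nv,
        grid.unit_cell.c / grid.nw,
    ])
    origin = np.array([m.header_float(i) for i in (50, 51, 52)])
    occ = (data > threshold).astype(np.uint8)
    return SkeletonGrid(occupancy=occ, spacing=spacing, origin=origin)


def write_skeleton(grid: SkeletonGrid, map_file: str | Path) -> None:
    """Write a :class:`SkeletonGrid` as an MRC map (values 0/1)."""
    nx, ny, nz = grid.shape
    g = gemmi.FloatGrid(nx, ny, nz)
    np.array(g, copy=False)[:] = grid.occupancy.astype(np.float32)
    g.set_unit_cell(gemmi.UnitCell(
        nx * grid.spacing[0], ny * grid.spacing[1], nz * grid.spacing[2],
        90.0, 90.0, 90.0))
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for i, v in zip((50, 51, 52), grid.origin):
        m.set_header_float(i, float(v))
    m.write_ccp4_map(str(map_file))


# ---------------------------------------------------------------------------
# stick / segment tables
# ---------------------------------------------------------------------------

_STICK_HEADER = "# stick\tindex\ttype\tx0\ty0\tz0\tx1\ty1\tz1"
_SEGMENT_HEADER = "# segment\tindex\ttype\tfirst_res\tlast_res"


def write_sticks(sticks: Sequence[Stick], table_file: str | Path) -> None:
    lines = [_STICK_HEADER]
    for s in sticks:
        coords = "\t".join(f"{v:.4f}" for v in (*s.p0, *s.p1))
        lines.append(f"{s.stick_index}\t{s.sse_type}\t{coords}")
    Path(table_file).write_text("\n".join(lines) + "\n")


def read_sticks(table_file: str | Path) -> list[Stick]:
    """Read a stick table; enforces the helix-before-strand ordering.

    If the file lists a helix after a strand, sticks are stably reordered
    (helices first) and renumbered, with a warning.
    """
    raw: list[tuple[str, np.ndarray, np.ndarray]] = []
    for ln, line in enumerate(Path(table_file).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 8:
            raise StructureError(f"{table_file}:{ln}: expected 8 columns, got {len(parts)}")
        typ = _TYPE_TOKENS.get(parts[1].upper())
        if typ is None:
            raise StructureError(f"{table_file}:{ln}: bad type token {parts[1]!r}")
        try:
            vals = [float(v) for v in parts[2:8]]
        except ValueError as exc:
            raise StructureError(f"{table_file}:{ln}: {exc}") from None
        raw.append((typ, np.array(vals[:3]), np.array(vals[3:])))
    ordered = [r for r in raw if r[0] == HELIX] + [r for r in raw if r[0] == STRAND]
    if [r[0] for r in raw] != [r[0] for r in ordered]:
        logger.warning("%s: helix sticks must precede strand sticks; reordered", table_file)
    return [Stick(k + 1, typ, p0, p1) for k, (typ, p0, p1) in enumerate(ordered)]


def write_segments(segments: Sequence[SequenceSegment], table_file: str | Path) -> None:
    lines = [_SEGMENT_HEADER]
    for s in segments:
        lines.append(f"{s.order_index}\t{s.sse_type}\t{s.first_res}\t{s.last_res}")
    Path(table_file).write_text("\n".join(lines) + "\n")


def read_segments(table_file: str | Path) -> list[SequenceSegment]:
    out: list[SequenceSegment] = []
    for ln, line in enumerate(Path(table_file).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise StructureError(f"{table_file}:{ln}: expected 4 columns, got {len(parts)}")
        typ = _TYPE_TOKENS.get(parts[1].upper())
        if typ is None:
            raise StructureError(f"{table_file}:{ln}: bad type token {parts[1]!r}")
        out.append(SequenceSegment(int(parts[0]), typ, int(parts[2]), int(parts[3])))
    return out


# ---------------------------------------------------------------------------
# writing chains (used by the synthetic-fixture generator)
# ---------------------------------------------------------------------------

def write_chain_pdb(
    chain: ChainModel,
    pdb_file: str | Path,
    annotation: Sequence[tuple[str, int, int]] = (),
) -> None:
    """Write a chain (with optional HELIX/SHEET records) as a PDB file."""
    st = gemmi.Structure()
    st.name = "ssetop"
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain.chain_id)
    for r in chain.residues:
        res = gemmi.Residue()
        res.name = _AA1TO3.get(r.aa, "ALA")
        res.seqid = gemmi.SeqId(r.index, " ")
        for name, pos in (("N", r.n), ("CA", r.ca), ("C", r.c)):
            if pos is None:
                continue
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(name[0])
            at.pos = gemmi.Position(*map(float, pos))
            res.add_atom(at)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    res_name = {r.index: _AA1TO3.get(r.aa, "ALA") for r in chain.residues}
    sheet = gemmi.Sheet("S1")
    n_strand = 0
    for typ, first, last in annotation:
        typ = _TYPE_TOKENS[str(typ).upper()]
        if typ == HELIX:
            h = gemmi.Helix()
            h.start = gemmi.AtomAddress(chain.chain_id, gemmi.SeqId(first, " "),
                                        res_name[first], "")
            h.end = gemmi.AtomAddress(chain.chain_id, gemmi.SeqId(last, " "),
                                      res_name[last], "")
            h.pdb_helix_class = 1
            h.length = last - first + 1
            st.helices.append(h)
        else:
            strand = gemmi.Sheet.Strand()
            strand.start = gemmi.AtomAddress(chain.chain_id, gemmi.SeqId(first, " "),
                                             res_name[first], "")
            strand.end = gemmi.AtomAddress(chain.chain_id, gemmi.SeqId(last, " "),
                                           res_name[last], "")
            strand.sense = 0
            n_strand += 1
            strand.name = str(n_strand)
            sheet.strands.append(strand)
    if n_strand:
        st.sheets.append(sheet)
    st.write_pdb(str(pdb_file))
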