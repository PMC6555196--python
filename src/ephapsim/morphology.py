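"""Neuron geometry: sections, cells, networks, discretization, SWC import.

Cells are built NEURON-style from *sections* — spheres for somata and
cylinders for axons/dendrites — connected end to end into a tree.
``discretize`` splits every cylinder into ``nseg`` equal segments (the
solution nodes of the cable equation) and assigns symmetric axial
resistances using the standard half-segment series rule,

    R_axial = ra * l / (pi r^2),

with ``ra`` the axial resistivity (ohm*cm) and ``l`` the series path length
(half of each adjacent segment).  Spheres are treated as isopotential: a
sphere couples to an attached cylinder through the cylinder's half-segment
resistance only.

All geometry is 3-D Cartesian in um; section "end 0" is the proximal point,
"end 1" the distal point.
"""

from __future__ import annotations

import copy
import io
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, NamingError, ValidationError
from .units import OHM_CM_UM_TO_MOHM

__all__ = [
    "Section",
    "Segment",
    "Cell",
    "Network",
    "connect",
    "discretize",
    "place",
    "read_swc",
    "write_swc",
    "fixture_network",
    "sphere",
    "cylinder",
]

_UNIT_TOL = 1e-9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Section:
    """A geometric primitive: a sphere (soma) or a cylinder (neurite).

    Parameters
    ----------
    name : str
        Identifier, unique within a cell.
    kind : {'sphere', 'cylinder'}
    radius : float
        Radius in um (> 0).
    length : float or None
        Cylinder length in um; ``None`` for spheres.
    proximal_point : (3,) array
        End-0 coordinate (sphere center for spheres), um.
    orientation : (3,) array or None
        Unit vector from proximal to distal end (cylinders only).
    nseg : int
        Number of solution segments (1 for spheres).
    cm : float
        Specific membrane capacitance, uF/cm^2.
    ra : float
        Axial resistivity, ohm*cm.
    model_tag : str
        Name of the membrane model bound to every segment of this section.
    """

    name: str
    kind: str
    radius: float
    length: float | None = None
    proximal_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray | None = None
    nseg: int = 1
    cm: float = 1.0
    ra: float = 100.0
    model_tag: str = "hh"

    def __post_init__(self) -> None:
        self.proximal_point = np.asarray(self.proximal_point, dtype=float)
        if self.kind not in ("sphere", "cylinder"):
            raise ValidationError(f"unknown section kind {self.kind!r}")
        if self.radius <= 0:
            raise ValidationError(f"section {self.name!r}: radius must be > 0")
        if self.nseg < 1:
            raise ValidationError(f"section {self.name!r}: nseg must be >= 1")
        if self.kind == "sphere":
            if self.nseg != 1:
                raise ValidationError(
                    f"sphere section {self.name!r} must have nseg = 1")
            self.length = None
            self.orientation = None
        else:
            if self.length is None or self.length <= 0:
                raise ValidationError(
                    f"cylinder {self.name!r}: length must be > 0")
            if self.orientation is None:
                raise ValidationError(
                    f"cylinder {self.name!r}: orientation required")
            self.orientation = np.asarray(self.orientation, dtype=float)
            norm = np.linalg.norm(self.orientation)
            if abs(norm - 1.0) > _UNIT_TOL:
                raise ValidationError(
                    f"cylinder {self.name!r}: orientation must be a unit "
                    f"vector (|v| = {norm:.12g})")

    def end_point(self, end: int) -> np.ndarray:
        """Coordinate of end 0 (proximal) or 1 (distal), um."""
        if self.kind == "sphere" or end == 0:
            return self.proximal_point.copy()
        return self.proximal_point + self.length * self.orientation

    @property
    def area(self) -> float:
        """Total membrane area, um^2 (lateral surface for cylinders)."""
        if self.kind == "sphere":
            return 4.0 * math.pi * self.radius ** 2
        return 2.0 * math.pi * self.radius * self.length


def sphere(name: str, radius: float, center=(0.0, 0.0, 0.0), **kw) -> Section:
    """Convenience constructor for a spherical (soma) section."""
    return Section(name=name, kind="sphere", radius=radius,
                   proximal_point=np.asarray(center, float), **kw)


def cylinder(name: str, radius: float, length: float,
             proximal_point=(0.0, 0.0, 0.0), orientation=(1.0, 0.0, 0.0),
             nseg: int = 1, **kw) -> Section:
    """Convenience constructor for a cylindrical (neurite) section."""
    return Section(name=name, kind="cylinder", radius=radius, length=length,
                   proximal_point=np.asarray(proximal_point, float),
                   orientation=np.asarray(orientation, float),
                   nseg=nseg, **kw)


@dataclass
class Segment:
    """A discretized solution node with its geometry and axial couplings."""

    id: int
    cell_index: int
    parent_section: str
    kind: str
    radius: float
    length: float          # um; 0 for spheres
    center: np.ndarray
    axis_start: np.ndarray
    axis_end: np.ndarray
    area: float            # um^2
    cm: float              # uF/cm^2
    model_tag: str
    neighbors: list[tuple[int, float]] = field(default_factory=list)
    # (neighbor segment id, axial resistance in Mohm); symmetric


@dataclass
class Cell:
    """An ordered collection of sections plus their tree connectivity."""

    name: str
    sections: list[Section] = field(default_factory=list)
    connections: list[tuple[str, int, str, int]] = field(default_factory=list)

    def add_section(self, spec: Section) -> "Cell":
        if any(s.name == spec.name for s in self.sections):
            raise NamingError(
                f"cell {self.name!r} already has a section {spec.name!r}")
        self.sections.append(spec)
        return self

    def section(self, name: str) -> Section:
        for s in self.sections:
            if s.name == name:
                return s
        raise NamingError(f"cell {self.name!r} has no section {name!r}")


def connect(cell: Cell, sec_a: str, end_a: int, sec_b: str, end_b: int) -> Cell:
    """Record an axial connection between two section ends.

    The section graph must stay acyclic (a tree per cell); a connection
    whose two sections are already connected (directly or transitively)
    raises :class:`ValidationError`.
    """
    if end_a not in (0, 1) or end_b not in (0, 1):
        raise ValidationError("connection ends must be 0 or 1")
    cell.section(sec_a)
    cell.section(sec_b)
    if sec_a == sec_b:
        raise ValidationError(f"cannot connect section {sec_a!r} to itself")
    # union-find over sections to reject cycles
    parent = {s.name: s.name for s in cell.sections}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, _, b, _ in cell.connections:
        parent[find(a)] = find(b)
    if find(sec_a) == find(sec_b):
        raise ValidationError(
            f"connection {sec_a!r}-{sec_b!r} would create a cycle")
    cell.connections.append((sec_a, end_a, sec_b, end_b))
    return cell


@dataclass
class Network:
    """Cells placed in space plus the flat segment list after discretization."""

    cells: list[Cell] = field(default_factory=list)
    segments: list[Segment] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def add(self, cell: Cell, offset=(0.0, 0.0, 0.0), rotation=None) -> "Network":
        return place(self, cell, offset, rotation)

    def cell_of(self, seg_id: int) -> int:
        return self.segments[seg_id].cell_index

    def segment_centers(self) -> np.ndarray:
        return np.array([s.center for s in self.segments])


def place(network: Network, cell: Cell, offset=(0.0, 0.0, 0.0),
          rotation=None) -> Network:
    """Add a deep copy of ``cell`` transformed by ``rotation`` then ``offset``."""
    offset = np.asarray(offset, dtype=float)
    if rotation is None:
        rotation = np.eye(3)
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3) or not np.allclose(
            rotation @ rotation.T, np.eye(3), atol=1e-9):
        raise ValidationError("rotation must be a 3x3 orthonormal matrix")
    placed = copy.deepcopy(cell)
    for sec in placed.sections:
        sec.proximal_point = rotation @ sec.proximal_point + offset
        if sec.orientation is not None:
            sec.orientation = rotation @ sec.orientation
    network.cells.append(placed)
    network.segments = []  # placement invalidates a previous discretization
    return network


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def _half_resistance(sec: Section) -> float:
    """Axial resistance (Mohm) of half of one segment; 0 for spheres."""
    if sec.kind == "sphere":
        return 0.0
    seg_len = sec.length / sec.nseg
    return sec.ra * (seg_len / 2.0) / (math.pi * sec.radius ** 2) \
        * OHM_CM_UM_TO_MOHM


def discretize(network: Network) -> Network:
    """Split sections into segments and build the axial resistance graph.

    Segment ids are global, consecutive and 0-based across the network, in
    cell order then section order then proximal-to-distal order.
    """
    segments: list[Segment] = []
    for ci, cell in enumerate(network.cells):
        # build this cell's segments
        end_seg: dict[tuple[str, int], int] = {}
        first_of_cell = len(segments)
        for sec in cell.sections:
            if sec.kind == "sphere":
                sid = len(segments)
                c = sec.proximal_point.copy()
                segments.append(Segment(
                    id=sid, cell_index=ci, parent_section=sec.name,
                    kind="sphere", radius=sec.radius, length=0.0,
                    center=c, axis_start=c.copy(), axis_end=c.copy(),
                    area=sec.area, cm=sec.cm, model_tag=sec.model_tag))
                end_seg[(sec.name, 0)] = sid
                end_seg[(sec.name, 1)] = sid
            else:
                seg_len = sec.length / sec.nseg
                r_int = 2.0 * _half_resistance(sec)  # full-segment resistance
                area = 2.0 * math.pi * sec.radius * seg_len
                base = len(segments)
                for k in range(sec.nseg):
                    a = sec.proximal_point + k * seg_len * sec.orientation
                    b = a + seg_len * sec.orientation
                    segments.append(Segment(
                        id=base + k, cell_index=ci, parent_section=sec.name,
                        kind="cylinder", radius=sec.radius, length=seg_len,
                        center=0.5 * (a + b), axis_start=a, axis_end=b,
                        area=area, cm=sec.cm, model_tag=sec.model_tag))
                    if k > 0:
                        _link(segments, base + k - 1, base + k, r_int)
                end_seg[(sec.name, 0)] = base
                end_seg[(sec.name, 1)] = base + sec.nseg - 1
        # connections between sections
        secs = {s.name: s for s in cell.sections}
        for (na, ea, nb, eb) in cell.connections:
            r = _half_resistance(secs[na]) + _half_resistance(secs[nb])
            if r <= 0.0:
                raise ValidationError(
                    f"cell {cell.name!r}: connection {na!r}-{nb!r} joins two "
                    "spheres (no axial path)")
            _link(segments, end_seg[(na, ea)], end_seg[(nb, eb)], r)
        # connectivity check (one component per cell)
        ids = list(range(first_of_cell, len(segments)))
        if ids and not _connected(segments, ids):
            raise ValidationError(
                f"cell {cell.name!r} is disconnected after discretization")
    network.segments = segments
    return network


def _link(segments: list[Segment], i: int, j: int, r: float) -> None:
    segments[i].neighbors.append((j, r))
    segments[j].neighbors.append((i, r))


def _connected(segments: list[Segment], ids: list[int]) -> bool:
    idset = set(ids)
    seen = {ids[0]}
    stack = [ids[0]]
    while stack:
        for j, _ in segments[stack.pop()].neighbors:
            if j in idset and j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == len(ids)


# ---------------------------------------------------------------------------
# SWC import / export
# ---------------------------------------------------------------------------

def read_swc(stream, name: str = "swc_cell", nseg: int = 1, cm: float = 1.0,
             ra: float = 100.0, model_tag: str = "hh") -> Cell:
    """Parse a standard 7-column SWC morphology into a :class:`Cell`.

    Type-1 (soma) records are collapsed into a single equivalent sphere of
    equal total surface area placed at the radius-weighted soma centroid.
    Every other record becomes a cylinder section from its parent's
    coordinate to its own, with the record's radius.

    ``stream`` may be a file-like object, a path, or the SWC text itself.
    """
    if isinstance(stream, str):
        if "\n" in stream or stream.lstrip().startswith("#"):
            stream = io.StringIO(stream)
        else:
            stream = open(stream)
    records: dict[int, tuple[int, np.ndarray, float, int]] = {}
    order: list[int] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise FormatError(f"SWC line {lineno}: expected 7 columns")
        try:
            rid, rtype = int(parts[0]), int(parts[1])
            xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
            radius = float(parts[5])
            parent = int(parts[6])
        except ValueError as exc:
            raise FormatError(f"SWC line {lineno}: non-numeric field") from exc
        if parent != -1 and parent not in records:
            raise FormatError(
                f"SWC line {lineno}: parent {parent} precedes its definition "
                "or is absent")
        if parent == -1 and order:
            raise FormatError(
                f"SWC line {lineno}: parent -1 on a non-first record")
        records[rid] = (rtype, xyz, radius, parent)
        order.append(rid)
    if not order:
        raise FormatError("empty SWC stream")

    cell = Cell(name=name)
    soma_ids = [r for r in order if records[r][0] == 1]
    rec_section: dict[int, tuple[str, int]] = {}  # record id -> (section, end)
    if soma_ids:
        pts = np.array([records[r][1] for r in soma_ids])
        radii = np.array([records[r][2] for r in soma_ids])
        r_eq = float(np.sqrt(np.sum(radii ** 2)))  # equal total 4*pi*r^2 area
        center = pts.mean(axis=0)
        cell.add_section(sphere("soma", r_eq, center, cm=cm, ra=ra,
                                model_tag=model_tag))
        for r in soma_ids:
            rec_section[r] = ("soma", 1)
    for rid in order:
        rtype, xyz, radius, parent = records[rid]
        if rtype == 1:
            continue
        if parent == -1:
            # a rootless neurite record: represent as a zero-parent stub is
            # not meaningful; require a parent for non-soma records
            raise FormatError(f"SWC record {rid}: non-soma record has no parent")
        if records[parent][0] == 1:
            start = cell.section("soma").proximal_point
            parent_sec, parent_end = rec_section[parent]
        else:
            start = records[parent][1]
            parent_sec, parent_end = rec_section[parent]
        vec = xyz - start
        length = float(np.linalg.norm(vec))
        if length <= 0:
            raise FormatError(f"SWC record {rid}: zero-length branch")
        sec_name = f"n{rid}"
        cell.add_section(cylinder(sec_name, radius, length,
                                  proximal_point=start,
                                  orientation=vec / length, nseg=nseg,
                                  cm=cm, ra=ra, model_tag=model_tag))
        connect(cell, sec_name, 0, parent_sec, parent_end)
        rec_section[rid] = (sec_name, 1)
    return cell


def write_swc(cell: Cell, stream=None) -> str:
    """Serialize a cell back to SWC text (one record per section).

    Inverse of :func:`read_swc` for cells made of one soma sphere plus
    single-record cylinders; topology and coordinates round-trip.
    """
    lines = [f"# {cell.name}"]
    sec_record: dict[str, int] = {}
    next_id = 1
    parent_of: dict[str, tuple[str, int]] = {}
    for (na, ea, nb, eb) in cell.connections:
        # record the earlier-added section as parent of the later one
        ia = [s.name for s in cell.sections].index(na)
        ib = [s.name for s in cell.sections].index(nb)
        if ia < ib:
            parent_of[nb] = (na, ea)
        else:
            parent_of[na] = (nb, eb)
    for sec in cell.sections:
        rid = next_id
        next_id += 1
        sec_record[sec.name] = rid
        if sec.kind == "sphere":
            rtype, xyz, parent = 1, sec.proximal_point, -1
        else:
            rtype = 3
            xyz = sec.end_point(1)
            pname, _ = parent_of.get(sec.name, (None, None))
            parent = sec_record[pname] if pname is not None else -1
        lines.append(
            f"{rid} {rtype} {xyz[0]:.9g} {xyz[1]:.9g} {xyz[2]:.9g} "
            f"{sec.radius:.9g} {parent}")
    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# canonical fixture geometries
# ---------------------------------------------------------------------------

#: default fixture parameters (um unless noted)
AXON_LENGTH = 1000.0
AXON_DIAMETER = 2.0
AXON_NSEG = 41
BUNDLE_PITCH = 5.0
BUNDLE_NSEG = 15
SOMA_RADIUS = 10.0


def _axon_cell(name="axon", length=AXON_LENGTH, diameter=AXON_DIAMETER,
               nseg=AXON_NSEG, model_tag="hh", origin=(0.0, 0.0, 0.0),
               orientation=(1.0, 0.0, 0.0)) -> Cell:
    cell = Cell(name=name)
    cell.add_section(cylinder("axon", diameter / 2.0, length,
                              proximal_point=origin, orientation=orientation,
                              nseg=nseg, model_tag=model_tag))
    return cell


def fixture_network(kind: str, **params) -> Network:
    """Deterministic canonical geometries used throughout validation.

    Kinds
    -----
    ``axon``
        One straight cylinder (default L = 1000 um, d = 2 um, nseg = 41).
    ``ball_and_stick``
        Spherical soma (r = 10 um) with the axon attached at end 0.
    ``bipolar``
        Soma with two symmetric axons in opposite directions.
    ``branched``
        Soma, a primary axon, and two daughter branches at its distal end.
    ``pair``
        Two parallel axons separated by ``pitch`` (default 5 um).
    ``hex_bundle``
        Seven parallel axons: one on the bundle axis and six at the vertices
        of a regular hexagon of circumradius ``pitch``; every outer axon is
        exactly ``pitch`` from the center and from its two ring neighbors.
    """
    length = params.pop("length", AXON_LENGTH)
    diameter = params.pop("diameter", AXON_DIAMETER)
    model_tag = params.pop("model_tag", "hh")
    net = Network()

    if kind == "axon":
        nseg = params.pop("nseg", AXON_NSEG)
        _reject_extras(kind, params)
        net.add(_axon_cell(length=length, diameter=diameter, nseg=nseg,
                           model_tag=model_tag))
    elif kind == "ball_and_stick":
        nseg = params.pop("nseg", AXON_NSEG)
        soma_radius = params.pop("soma_radius", SOMA_RADIUS)
        _reject_extras(kind, params)
        cell = Cell(name="ball_and_stick")
        cell.add_section(sphere("soma", soma_radius, model_tag=model_tag))
        cell.add_section(cylinder("axon", diameter / 2.0, length,
                                  proximal_point=(soma_radius, 0.0, 0.0),
                                  orientation=(1.0, 0.0, 0.0), nseg=nseg,
                                  model_tag=model_tag))
        connect(cell, "axon", 0, "soma", 1)
        net.add(cell)
    elif kind == "bipolar":
        nseg = params.pop("nseg", AXON_NSEG)
        soma_radius = params.pop("soma_radius", SOMA_RADIUS)
        _reject_extras(kind, params)
        cell = Cell(name="bipolar")
        cell.add_section(sphere("soma", soma_radius, model_tag=model_tag))
        for label, sgn in (("axon_pos", 1.0), ("axon_neg", -1.0)):
            cell.add_section(cylinder(
                label, diameter / 2.0, length,
                proximal_point=(sgn * soma_radius, 0.0, 0.0),
                orientation=(sgn, 0.0, 0.0), nseg=nseg, model_tag=model_tag))
            connect(cell, label, 0, "soma", 1 if sgn > 0 else 0)
        net.add(cell)
    elif kind == "branched":
        nseg = params.pop("nseg", 21)
        soma_radius = params.pop("soma_radius", SOMA_RADIUS)
        _reject_extras(kind, params)
        cell = Cell(name="branched")
        cell.add_section(sphere("soma", soma_radius, model_tag=model_tag))
        cell.add_section(cylinder("trunk", diameter / 2.0, length / 2.0,
                                  proximal_point=(soma_radius, 0.0, 0.0),
                                  orientation=(1.0, 0.0, 0.0), nseg=nseg,
                                  model_tag=model_tag))
        connect(cell, "trunk", 0, "soma", 1)
        tip = np.array([soma_radius + length / 2.0, 0.0, 0.0])
        s, c = math.sin(math.pi / 6.0), math.cos(math.pi / 6.0)
        for label, sy in (("daughter_up", s), ("daughter_down", -s)):
            cell.add_section(cylinder(label, diameter / 2.0, length / 2.0,
                                      proximal_point=tip,
                                      orientation=(c, sy, 0.0), nseg=nseg,
                                      model_tag=model_tag))
            connect(cell, label, 0, "trunk", 1)
        net.add(cell)
    elif kind == "pair":
        nseg = params.pop("nseg", AXON_NSEG)
        pitch = params.pop("pitch", BUNDLE_PITCH)
        _reject_extras(kind, params)
        for i in range(2):
            net.add(_axon_cell(name=f"axon_{i}", length=length,
                               diameter=diameter, nseg=nseg,
                               model_tag=model_tag),
                    offset=(0.0, i * pitch, 0.0))
    elif kind == "hex_bundle":
        nseg = params.pop("nseg", BUNDLE_NSEG)
        pitch = params.pop("pitch", BUNDLE_PITCH)
        _reject_extras(kind, params)
        offsets = [(0.0, 0.0, 0.0)]
        for k in range(6):
            ang = k * math.pi / 3.0
            offsets.append((0.0, pitch * math.cos(ang), pitch * math.sin(ang)))
        for i, off in enumerate(offsets):
            net.add(_axon_cell(name=f"axon_{i}", length=length,
                               diameter=diameter, nseg=nseg,
                               model_tag=model_tag), offset=off)
    else:
        raise ValidationError(f"unknown fixture kind {kind!r}")
    return discretize(net)


def _reject_extras(kind: str, params: dict) -> None:
    if params:
        raise ValidationError(
            f"fixture {kind!r}: unknown parameters {sorted(params)}")
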