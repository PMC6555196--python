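"""Extracellular potentials from compartment membrane currents.

The extracellular medium is homogeneous, isotropic and purely ohmic with
conductivity sigma (S/m), so the potential obeys a Poisson equation whose
closed-form elementary solutions are used directly (no finite elements):

* cylinder segments are *line sources*: a current I spread uniformly along
  the axis of a cylinder of length L gives, at perpendicular distance r and
  signed axial coordinates l (from the beginning) and h = l - L (from the
  end),

      V = I / (4 pi sigma L) * ln| (sqrt(h^2+r^2) - h) / (sqrt(l^2+r^2) - l) |

* sphere segments are *point (spherical) sources*: V = I / (4 pi sigma R)
  outside the sphere, clamped to the surface value for R < r_sphere (the
  exterior solution; the clamp keeps self-coefficients finite).

Linearity of the Poisson equation means superposition holds exactly: the
potential of a network is the sum of single-segment contributions.  The
per-segment extracellular potential that feeds back into the membrane
dynamics is the kernel *averaged over the boundary* (lateral surface /
surface ring) of the receiving segment; the resulting dense matrix of
coefficients (mV per nA, scaling exactly as 1/sigma) is the
:class:`TransferMatrix`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import SingularityError, ValidationError
from .morphology import Network, Segment
from .units import POINT_SOURCE_MV

__all__ = [
    "ExtracellularMedium",
    "FieldGeometry",
    "SamplingSpec",
    "TransferMatrix",
    "ProbeGrid",
    "line_source_potential",
    "point_source_potential",
    "boundary_averaged_coefficient",
    "build_transfer_matrix",
    "evaluate_probes",
    "probe_matrix",
    "quadrature_probe_matrix",
    "extracellular_pattern",
]

_AXIS_TOL = 1e-9


@dataclass
class ExtracellularMedium:
    """Homogeneous, isotropic ohmic medium."""

    sigma: float  # S/m

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")


@dataclass
class FieldGeometry:
    """Evaluation-point geometry relative to a single source.

    For cylinders: ``r`` is the perpendicular distance from the axis, ``l``
    the signed axial distance from the cylinder beginning, ``h = l - L`` the
    signed distance from the end.  For spheres: ``R`` is the distance from
    the center and ``r`` the sphere radius.
    """

    r: float = 0.0
    l: float = 0.0
    h: float = 0.0
    R: float = 0.0
    L: float = 0.0


@dataclass
class SamplingSpec:
    """Boundary-averaging sample layout (lateral surfaces only)."""

    n_axial: int = 5
    n_azimuth: int = 8

    def __post_init__(self):
        if self.n_axial < 1 or self.n_azimuth < 1:
            raise ValidationError("sampling requires >= 1 point per direction")


@dataclass
class TransferMatrix:
    """Dense (n_targets x n_sources) map, mV of boundary-averaged Vout per
    nA of source membrane current, at a fixed sigma."""

    entries: np.ndarray
    sigma_used: float
    sampling: SamplingSpec = field(default_factory=SamplingSpec)


@dataclass
class ProbeGrid:
    """Explicit extracellular recording points."""

    points: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValidationError("probe points must be 3-vectors")
        uniq = {tuple(np.round(p, 12)) for p in self.points}
        if len(uniq) != len(self.points):
            raise ValidationError("probe points must be distinct")
        if self.labels is None:
            self.labels = [f"p{i}" for i in range(len(self.points))]


# ---------------------------------------------------------------------------
# elementary kernels (coefficients in mV per nA)
# ---------------------------------------------------------------------------

def _sqrt_plus(a: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """sqrt(a^2 + r^2) + a, evaluated without cancellation for a < 0."""
    s = np.sqrt(a * a + r2)
    return np.where(a >= 0, s + a, r2 / (s - a))


def _line_coefficient(r, l, h, sigma):
    """Line-source potential coefficient (mV/nA); vectorized.

    Equivalent to (1 / 4 pi sigma L) * ln|(sqrt(h^2+r^2)-h)/(sqrt(l^2+r^2)-l)|
    evaluated in the cancellation-free form ln(f(l)/f(h)), f(a)=sqrt(a^2+r^2)+a.
    """
    r = np.asarray(r, dtype=float)
    l = np.asarray(l, dtype=float)
    h = np.asarray(h, dtype=float)
    L = l - h
    r2 = r * r
    on_axis = r < _AXIS_TOL
    if np.any(on_axis & (l > -_AXIS_TOL) & (h < _AXIS_TOL)):
        raise SingularityError(
            "line-source potential requested on the singular axis segment")
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.log(_sqrt_plus(l, r2) / _sqrt_plus(h, r2))
    if np.any(on_axis):
        # on the extended axis but outside the source: exact limit r -> 0
        val = np.where(on_axis, np.abs(np.log(np.abs(l / h))), val)
    return POINT_SOURCE_MV * val / (sigma * L)


def line_source_potential(i_na: float, geom: FieldGeometry,
                          medium: ExtracellularMedium) -> float:
    """Potential (mV) of a uniform line source carrying ``i_na`` (nA)."""
    if i_na == 0.0:
        return 0.0
    c = _line_coefficient(np.array([geom.r]), np.array([geom.l]),
                          np.array([geom.h]), medium.sigma)
    return float(i_na * c[0])


def _point_coefficient(R, r_sphere, sigma):
    R = np.asarray(R, dtype=float)
    return POINT_SOURCE_MV / (sigma * np.maximum(R, r_sphere))


def point_source_potential(i_na: float, R: float, r_sphere: float,
                           medium: ExtracellularMedium) -> float:
    """Potential (mV) of a spherical source at distance ``R`` from its
    center; for R < r_sphere the surface value is returned."""
    return float(i_na * _point_coefficient(R, r_sphere, medium.sigma))


def _segment_coefficients(seg: Segment, points: np.ndarray,
                          sigma: float) -> np.ndarray:
    """Kernel coefficient (mV/nA) of one source segment at many points."""
    points = np.atleast_2d(points)
    if seg.kind == "sphere":
        R = np.linalg.norm(points - seg.center, axis=1)
        return _point_coefficient(R, seg.radius, sigma)
    d = seg.axis_end - seg.axis_start
    L = np.linalg.norm(d)
    u = d / L
    rel = points - seg.axis_start
    l = rel @ u
    r = np.linalg.norm(rel - np.outer(l, u), axis=1)
    return _line_coefficient(r, l, l - L, sigma)


# ---------------------------------------------------------------------------
# boundary averaging and the transfer matrix
# ---------------------------------------------------------------------------

def _orthonormal_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to u."""
    a = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(u, e1)


def _sphere_ring_axis(seg: Segment, network: Network | None) -> np.ndarray:
    """Deterministic, geometry-anchored axis for a sphere's sample ring
    (co-rotates with the network so coefficients are isometry-invariant)."""
    if network is not None and seg.neighbors:
        nb = network.segments[seg.neighbors[0][0]]
        v = nb.center - seg.center
        n = np.linalg.norm(v)
        if n > 0:
            return v / n
    return np.array([0.0, 0.0, 1.0])


def segment_sample_points(seg: Segment, sampling: SamplingSpec,
                          network: Network | None = None) -> np.ndarray:
    """Boundary sample points: lateral-surface grid for cylinders, a ring of
    ``n_azimuth`` points on a great circle for spheres."""
    if seg.kind == "sphere":
        u = _sphere_ring_axis(seg, network)
        e1, e2 = _orthonormal_frame(u)
        ang = 2.0 * math.pi * (np.arange(sampling.n_azimuth) + 0.5) \
            / sampling.n_azimuth
        return seg.center + seg.radius * (np.outer(np.cos(ang), e1)
                                          + np.outer(np.sin(ang), e2))
    d = seg.axis_end - seg.axis_start
    L = np.linalg.norm(d)
    u = d / L
    e1, e2 = _orthonormal_frame(u)
    ax = (np.arange(sampling.n_axial) + 0.5) / sampling.n_axial
    ang = 2.0 * math.pi * (np.arange(sampling.n_azimuth) + 0.5) \
        / sampling.n_azimuth
    ring = seg.radius * (np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2))
    pts = (seg.axis_start[None, None, :]
           + ax[:, None, None] * L * u[None, None, :]
           + ring[None, :, :])
    return pts.reshape(-1, 3)


def boundary_averaged_coefficient(source: Segment, target: Segment,
                                  medium: ExtracellularMedium,
                                  sampling: SamplingSpec | None = None,
                                  network: Network | None = None) -> float:
    """Mean of the source's kernel over the target's boundary samples
    (mV/nA).  For source == target the samples sit at the segment's own
    radius, so the self-coefficient is finite."""
    sampling = sampling or SamplingSpec()
    pts = segment_sample_points(target, sampling, network)
    return float(np.mean(_segment_coefficients(source, pts, medium.sigma)))


def build_transfer_matrix(network: Network, medium: ExtracellularMedium,
                          sampling: SamplingSpec | None = None) -> TransferMatrix:
    """Entry (i, j): boundary-averaged potential at segment i per nA of
    membrane current from segment j.  Dense, deterministic for a fixed
    sampling layout; every entry scales exactly as 1/sigma."""
    sampling = sampling or SamplingSpec()
    segs = network.segments
    n = len(segs)
    all_pts = [segment_sample_points(s, sampling, network) for s in segs]
    counts = np.array([len(p) for p in all_pts])
    stacked = np.concatenate(all_pts, axis=0)
    bounds = np.concatenate([[0], np.cumsum(counts)])
    entries = np.empty((n, n))
    for j, src in enumerate(segs):
        coefs = _segment_coefficients(src, stacked, medium.sigma)
        sums = np.add.reduceat(coefs, bounds[:-1])
        entries[:, j] = sums / counts
    return TransferMatrix(entries=entries, sigma_used=medium.sigma,
                          sampling=sampling)


# ---------------------------------------------------------------------------
# probes (open-loop LFP) and extracellular stimulation
# ---------------------------------------------------------------------------

def probe_matrix(network: Network, probes: ProbeGrid,
                 medium: ExtracellularMedium) -> np.ndarray:
    """(n_probes x n_segments) closed-form kernel coefficients (mV/nA)."""
    n = network.n_segments
    out = np.empty((len(probes.points), n))
    for j, src in enumerate(network.segments):
        try:
            out[:, j] = _segment_coefficients(src, probes.points, medium.sigma)
        except SingularityError as exc:
            raise SingularityError(
                f"a probe lies on the axis of segment {j}") from exc
    return out


def evaluate_probes(network: Network, currents: np.ndarray, probes: ProbeGrid,
                    medium: ExtracellularMedium) -> np.ndarray:
    """Post-hoc (open-loop) LFP: potentials (mV) at each probe and time.

    ``currents`` is (n_segments,) or (n_segments, n_times) of total membrane
    currents in nA; the result has shape (n_probes,) or (n_probes, n_times).
    """
    currents = np.asarray(currents, dtype=float)
    if currents.shape[0] != network.n_segments:
        raise ValidationError(
            "currents first dimension must equal the number of segments")
    return probe_matrix(network, probes, medium) @ currents


def quadrature_probe_matrix(network: Network, probes: ProbeGrid,
                            medium: ExtracellularMedium,
                            n_sub: int = 10000) -> np.ndarray:
    """Independent quadrature evaluation of the probe kernels: each cylinder
    is replaced by ``n_sub`` equal point sources along its axis (midpoint
    rule); spheres use the exact exterior point-source form.  Used as the
    oracle against the closed-form line-source path."""
    segs = network.segments
    out = np.empty((len(probes.points), len(segs)))
    for j, seg in enumerate(segs):
        if seg.kind == "sphere":
            R = np.linalg.norm(probes.points - seg.center, axis=1)
            out[:, j] = _point_coefficient(R, seg.radius, medium.sigma)
            continue
        frac = (np.arange(n_sub) + 0.5) / n_sub
        srcs = seg.axis_start[None, :] + frac[:, None] * (
            seg.axis_end - seg.axis_start)[None, :]
        d = np.linalg.norm(probes.points[:, None, :] - srcs[None, :, :], axis=2)
        if np.any(d < _AXIS_TOL):
            raise SingularityError(f"a probe coincides with segment {j}")
        out[:, j] = POINT_SOURCE_MV / (medium.sigma * n_sub) \
            * np.sum(1.0 / d, axis=1)
    return out


def extracellular_pattern(spec, points: np.ndarray,
                          medium: ExtracellularMedium) -> np.ndarray:
    """Potential (mV) per unit waveform value of an extracellular stimulus
    at the given points: point electrode -> point-source coefficients for
    1 nA; parallel plates -> V(x) = -e . x for a unit field magnitude."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if spec.electrode == "plates":
        e = np.asarray(spec.field_direction, dtype=float)
        e = e / np.linalg.norm(e)
        return -(points @ e)
    pos = np.asarray(spec.position, dtype=float)
    R = np.linalg.norm(points - pos, axis=1)
    if np.any(R < _AXIS_TOL):
        raise SingularityError(
            "field evaluation at the point-electrode location")
    return POINT_SOURCE_MV / (medium.sigma * R)
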