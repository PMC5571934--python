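"""Core parametric geometry of the mitral valve leaflets.

The valve is modelled as portions of two interfacing semi-elliptic
cylindrical shells that share the inter-commissural (IC) axis: the
anterior leaflet lives on the cylinder with semi-axes (IC/2, SL_ant)
and the posterior leaflet — three scallops P1, P2, P3 — on the cylinder
with semi-axes (IC/2, SL_post).  Each leaflet's free edge is a sine
curve in the cylinder's parameter plane.  All lengths are centimetres,
all angles radians.

A surface point is ``(a cos y1, b sin y1, h y2)`` where ``y1`` sweeps
the annulus angle and ``y2`` the normalised height.  The anterior patch
occupies ``y1 in [0, pi]`` with ``0 <= y2 <= sin(y1)``; the posterior
scallops tile ``[pi, 2*pi]`` in proportion to their widths, each with a
sine free edge whose frequency is fixed by the junction phase ``phi``
(default ``8*pi/9``) so that the free edge is height-continuous across
the scallop junctions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

__all__ = [
    "InvalidParameterError",
    "DomainError",
    "InfeasibleGeometryError",
    "AnnulusGeometry",
    "LeafletDimensions",
    "PosteriorPartition",
    "SurfacePoint",
    "ValveParameters",
    "DEFAULT_JUNCTION_PHASE",
    "elliptic_cylinder_point",
    "anterior_free_edge",
    "partition_posterior",
    "junction_offset",
    "posterior_scallop_bounds",
    "anterior_point",
    "posterior_point",
    "check_continuity",
]

ScallopId = Literal["P1", "P2", "P3"]
LeafletId = Literal["anterior", "P1", "P2", "P3"]

#: Junction phase: the sine phase at which a scallop free edge meets its
#: neighbour.  8*pi/9 reproduces the canonical frequencies 3, 54/23 and
#: 16/5 for the default widths 1.6/2.3/1.5 cm.
DEFAULT_JUNCTION_PHASE = 8.0 * math.pi / 9.0


class InvalidParameterError(ValueError):
    """A geometric parameter is outside its admissible range."""


class DomainError(ValueError):
    """A parameter-plane coordinate lies outside the patch domain."""


class InfeasibleGeometryError(InvalidParameterError):
    """Dimensions that cannot produce a continuous free edge."""


@dataclass(frozen=True)
class AnnulusGeometry:
    """The mitral annulus as two semi-ellipses sharing the IC axis.

    Parameters
    ----------
    ic : float
        Inter-commissural diameter (full width of the shared axis), cm.
    sl_ant : float
        Septolateral semi-depth of the anterior annulus, cm.
    sl_post : float
        Septolateral semi-depth of the posterior annulus, cm.
    """

    ic: float = 2.8
    sl_ant: float = 1.04
    sl_post: float = 2.11

    def __post_init__(self) -> None:
        for name in ("ic", "sl_ant", "sl_post"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive, got {getattr(self, name)!r}")

    @property
    def a(self) -> float:
        """Shared semi-axis along the IC direction, cm."""
        return self.ic / 2.0

    @property
    def septolateral_diameter(self) -> float:
        """Total annulus depth perpendicular to the IC axis, cm."""
        return self.sl_ant + self.sl_post


@dataclass(frozen=True)
class LeafletDimensions:
    """Heights and widths of the four leaflet regions (cm).

    Heights are the maximum z-reach of each region's free edge; widths
    are the measured leaflet widths used to partition the posterior
    annulus proportionally (``w_ant`` is informational only — the
    anterior region always spans its full semi-ellipse).

    The default P3 height is 1.1 cm, the coefficient of the P3 surface
    equation; the alternative tabulated value 1.0 cm may be configured
    explicitly.
    """

    h_ant: float = 2.4
    h_p1: float = 1.1
    h_p2: float = 1.4
    h_p3: float = 1.1
    w_ant: float = 3.6
    w_p1: float = 1.6
    w_p2: float = 2.3
    w_p3: float = 1.5

    def __post_init__(self) -> None:
        for name in ("h_ant", "h_p1", "h_p2", "h_p3", "w_ant", "w_p1", "w_p2", "w_p3"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive, got {getattr(self, name)!r}")

    def height(self, leaflet: LeafletId) -> float:
        return {"anterior": self.h_ant, "P1": self.h_p1, "P2": self.h_p2, "P3": self.h_p3}[leaflet]


@dataclass(frozen=True)
class SurfacePoint:
    """A point on a leaflet surface, cm."""

    x: float
    y: float
    z: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


def elliptic_cylinder_point(a: float, b: float, h: float, y1: float, y2: float) -> SurfacePoint:
    """Evaluate the elliptic-cylinder map ``(a cos y1, b sin y1, h y2)``.

    ``a``, ``b`` are the ellipse semi-axes (cm), ``h`` the cylinder
    height scale (cm); ``y1`` is the annulus angle (rad) and ``y2`` the
    dimensionless height coordinate.
    """
    if not (a > 0 and b > 0 and h > 0):
        raise InvalidParameterError(f"semi-axes and height must be positive, got a={a}, b={b}, h={h}")
    return SurfacePoint(a * math.cos(y1), b * math.sin(y1), h * y2)


def anterior_free_edge(y1: float) -> float:
    """Upper ``y2`` bound of the anterior patch: ``sin(y1)`` on [0, pi]."""
    if not 0.0 <= y1 <= math.pi:
        raise DomainError(f"anterior angle must lie in [0, pi], got {y1}")
    return math.sin(y1)


def partition_posterior(w_p1: float, w_p2: float, w_p3: float) -> tuple[float, float]:
    """Split [pi, 2*pi] among the scallops in proportion to their widths.

    Returns the junction angles ``(theta1, theta2)`` with
    ``theta1 = pi + pi*w_p1/S`` and ``theta2 = theta1 + pi*w_p2/S``
    where ``S`` is the total posterior width.
    """
    if not (w_p1 > 0 and w_p2 > 0 and w_p3 > 0):
        raise InvalidParameterError(f"scallop widths must be positive, got {(w_p1, w_p2, w_p3)}")
    total = w_p1 + w_p2 + w_p3
    theta1 = math.pi * (1.0 + w_p1 / total)
    theta2 = theta1 + math.pi * (w_p2 / total)
    return theta1, theta2


def junction_offset(h_p1: float, h_p2: float, phi: float) -> float:
    """Lower ``y2`` bound of P2 making its free edge start where P1's ends.

    The P1 free edge reaches ``z = h_p1 * sin(pi - phi)`` at the P1/P2
    junction; lifting the whole P2 band by ``delta = h_p1*sin(pi-phi)/h_p2``
    makes the edge continuous there.
    """
    if not (h_p1 > 0 and h_p2 > 0):
        raise InvalidParameterError(f"scallop heights must be positive, got {(h_p1, h_p2)}")
    if not 0.0 < phi <= math.pi:
        raise InvalidParameterError(f"junction phase must lie in (0, pi], got {phi}")
    delta = h_p1 * math.sin(math.pi - phi) / h_p2
    if delta >= 1.0:
        raise InfeasibleGeometryError(
            f"middle scallop shorter than the junction height (delta={delta:.4f} >= 1)"
        )
    return delta


@dataclass(frozen=True)
class PosteriorPartition:
    """Derived angular partition and free-edge coefficients of the posterior leaflet.

    ``theta1``/``theta2`` are the P1/P2 and P2/P3 junction angles;
    ``c1``, ``c2``, ``c3`` the sine frequencies; ``delta`` the P2
    lower-bound offset.  With the default dimensions these equal
    35*pi/27, 93*pi/54, 3, 54/23, 16/5 and (11/14)*sin(pi/9).
    """

    theta1: float
    theta2: float
    phi: float
    c1: float
    c2: float
    c3: float
    delta: float

    @classmethod
    def from_dims(cls, dims: LeafletDimensions, phi: float = DEFAULT_JUNCTION_PHASE) -> "PosteriorPartition":
        theta1, theta2 = partition_posterior(dims.w_p1, dims.w_p2, dims.w_p3)
        c1 = phi / (theta1 - math.pi)
        c2 = math.pi / (theta2 - theta1)
        c3 = phi / (2.0 * math.pi - theta2)
        delta = junction_offset(dims.h_p1, dims.h_p2, phi)
        return cls(theta1=theta1, theta2=theta2, phi=phi, c1=c1, c2=c2, c3=c3, delta=delta)

    def __post_init__(self) -> None:
        if not math.pi < self.theta1 < self.theta2 < 2.0 * math.pi:
            raise InvalidParameterError(
                f"junction angles must satisfy pi < theta1 < theta2 < 2*pi, got "
                f"({self.theta1}, {self.theta2})"
            )
        if not 0.0 <= self.delta < 1.0:
            raise InfeasibleGeometryError(f"offset delta must lie in [0, 1), got {self.delta}")

    def scallop_of(self, y1: float) -> ScallopId:
        """Scallop containing angle ``y1``; junction angles resolve rightward."""
        if not math.pi <= y1 <= 2.0 * math.pi:
            raise DomainError(f"posterior angle must lie in [pi, 2*pi], got {y1}")
        if y1 < self.theta1:
            return "P1"
        if y1 < self.theta2:
            return "P2"
        return "P3"

    def interval(self, scallop: ScallopId) -> tuple[float, float]:
        return {
            "P1": (math.pi, self.theta1),
            "P2": (self.theta1, self.theta2),
            "P3": (self.theta2, 2.0 * math.pi),
        }[scallop]


def posterior_scallop_bounds(
    y1: float, partition: PosteriorPartition
) -> tuple[float, float, ScallopId]:
    """Lower/upper ``y2`` bounds of the posterior patch at angle ``y1``.

    P1: ``[0, sin(c1 (y1-pi))]``; P2: ``[delta, delta + (1-delta) sin(c2 (y1-theta1))]``;
    P3: ``[0, sin(c3 (2 pi - y1))]``.
    """
    scallop = partition.scallop_of(y1)
    if scallop == "P1":
        return 0.0, math.sin(partition.c1 * (y1 - math.pi)), "P1"
    if scallop == "P2":
        d = partition.delta
        return d, d + (1.0 - d) * math.sin(partition.c2 * (y1 - partition.theta1)), "P2"
    return 0.0, math.sin(partition.c3 * (2.0 * math.pi - y1)), "P3"


@dataclass(frozen=True)
class ValveParameters:
    """Full parameter set of the valve model: annulus, dimensions, junction phase."""

    annulus: AnnulusGeometry = field(default_factory=AnnulusGeometry)
    dims: LeafletDimensions = field(default_factory=LeafletDimensions)
    phi: float = DEFAULT_JUNCTION_PHASE

    @property
    def partition(self) -> PosteriorPartition:
        # derived, cheap enough to recompute; frozen dataclass keeps it consistent
        return PosteriorPartition.from_dims(self.dims, self.phi)

    def with_dims(self, **changes: float) -> "ValveParameters":
        return replace(self, dims=replace(self.dims, **changes))


def anterior_point(params: ValveParameters, y1: float, y2: float) -> SurfacePoint:
    """Anterior-patch point; requires ``0 <= y2 <= sin(y1)`` with ``y1`` in [0, pi]."""
    upper = anterior_free_edge(y1)
    if not -1e-12 <= y2 <= upper + 1e-12:
        raise DomainError(f"y2={y2} outside anterior bounds [0, {upper}] at y1={y1}")
    ann = params.annulus
    return elliptic_cylinder_point(ann.a, ann.sl_ant, params.dims.h_ant, y1, y2)


def posterior_point(params: ValveParameters, y1: float, y2: float) -> SurfacePoint:
    """Posterior-patch point at angle ``y1`` and height coordinate ``y2``.

    ``y2`` may range from the annulus (0) up to the free edge; the P2
    band proper starts at the junction offset ``delta``, but the
    attachment region below it is still on the leaflet surface.
    """
    _, upper, scallop = posterior_scallop_bounds(y1, params.partition)
    if not -1e-12 <= y2 <= upper + 1e-12:
        raise DomainError(
            f"y2={y2} outside {scallop} range [0, {upper}] at y1={y1}"
        )
    ann = params.annulus
    return elliptic_cylinder_point(ann.a, ann.sl_post, params.dims.height(scallop), y1, y2)


def check_continuity(
    params: ValveParameters, partition: PosteriorPartition | None = None
) -> float:
    """Maximum free-edge height gap (cm) across the two scallop junctions.

    Any partition built through :func:`junction_offset` yields zero to
    floating tolerance; a manually overridden ``delta`` exposes the gap.
    """
    part = params.partition if partition is None else partition
    dims = params.dims
    # left/right limits of the free-edge z at each junction
    z_p1_end = dims.h_p1 * math.sin(part.c1 * (part.theta1 - math.pi))
    z_p2_start = dims.h_p2 * part.delta
    z_p2_end = dims.h_p2 * (
        part.delta + (1.0 - part.delta) * math.sin(part.c2 * (part.theta2 - part.theta1))
    )
    z_p3_start = dims.h_p3 * math.sin(part.c3 * (2.0 * math.pi - part.theta2))
    return max(abs(z_p1_end - z_p2_start), abs(z_p2_end - z_p3_start))
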