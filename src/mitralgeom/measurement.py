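"""Morphometric measurement and validation against published reference ranges.

Computes the quantities a valve morphologist reports — leaflet heights,
annulus diameters, arc widths, surface areas — either analytically from
the model parameters (the surfaces are developable, so areas reduce to
one-dimensional quadrature of band height times the ellipse arc
element) or from a triangulated mesh, and checks them against the
published population ranges for healthy adult mitral valves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.integrate import quad

from .meshing import TriangleMesh
from .valve_model import LeafletId, ValveParameters

__all__ = [
    "REFERENCE_RANGES",
    "Measurement",
    "MeasurementReport",
    "axis_extent",
    "leaflet_max_height",
    "annulus_arc_length",
    "surface_area",
    "validate_against_reference",
]

#: Published healthy-cohort leaflet dimensions, cm: {region: {"width"/"height": (central, lo, hi)}}.
REFERENCE_RANGES: dict[str, dict[str, tuple[float, float, float]]] = {
    "anterior": {"width": (3.6, 2.5, 4.8), "height": (2.4, 2.0, 3.0)},
    "P1": {"width": (1.6, 0.9, 4.0), "height": (1.1, 0.9, 2.0)},
    "P2": {"width": (2.3, 1.3, 3.8), "height": (1.4, 0.9, 2.0)},
    "P3": {"width": (1.5, 0.9, 3.1), "height": (1.0, 0.6, 1.7)},
}

REFERENCE_SOURCE = "healthy adult cohort (n=50)"

_QUAD_RTOL = 1e-9


@dataclass(frozen=True)
class Measurement:
    """One named morphometric scalar with an optional reference range."""

    name: str
    value: float
    unit: str
    lo: float | None = None
    hi: float | None = None
    source: str = ""

    @property
    def passed(self) -> bool | None:
        """In-range flag; ``None`` when no range applies."""
        if self.lo is None or self.hi is None:
            return None
        return self.lo <= self.value <= self.hi


@dataclass
class MeasurementReport:
    """A collection of measurements with range checks."""

    entries: list[Measurement]

    @property
    def passed(self) -> bool:
        """True when every range-checked entry is in range."""
        return all(m.passed is not False for m in self.entries)

    def __getitem__(self, name: str) -> Measurement:
        for m in self.entries:
            if m.name == name:
                return m
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": m.name,
                    "value": m.value,
                    "unit": m.unit,
                    "ref_lo": m.lo,
                    "ref_hi": m.hi,
                    "source": m.source,
                    "passed": m.passed,
                }
                for m in self.entries
            ]
        )

    def to_dict(self) -> dict:
        return {
            m.name: {
                "value": m.value,
                "unit": m.unit,
                "ref_lo": m.lo,
                "ref_hi": m.hi,
                "source": m.source,
                "passed": m.passed,
            }
            for m in self.entries
        }


def axis_extent(mesh: TriangleMesh, axis: str) -> float:
    """Extent (max - min, cm) of the mesh vertices along ``"x"``, ``"y"`` or ``"z"``."""
    if mesh.n_vertices == 0:
        raise ValueError("cannot measure an empty mesh")
    i = {"x": 0, "y": 1, "z": 2}[axis]
    coords = mesh.vertices[:, i]
    return float(coords.max() - coords.min())


def leaflet_max_height(params: ValveParameters, leaflet: LeafletId) -> float:
    """Analytic maximum height (cm) of one leaflet region's surface.

    The free edge is ``h * s(y1)`` with ``s`` a sine ramp; the maximum
    is ``h`` when the sine reaches 1 inside the region's angular
    interval, otherwise ``h`` times the boundary value of the sine.
    """
    dims = params.dims
    if leaflet == "anterior":
        return dims.h_ant  # sin attains 1 at y1 = pi/2, always interior
    part = params.partition
    if leaflet == "P1":
        span = part.c1 * (part.theta1 - math.pi)
        return dims.h_p1 * (1.0 if span >= math.pi / 2.0 else math.sin(span))
    if leaflet == "P2":
        span = part.c2 * (part.theta2 - part.theta1)
        s = 1.0 if span >= math.pi / 2.0 else math.sin(span)
        return dims.h_p2 * (part.delta + (1.0 - part.delta) * s)
    span = part.c3 * (2.0 * math.pi - part.theta2)
    return dims.h_p3 * (1.0 if span >= math.pi / 2.0 else math.sin(span))


def _arc_element(a: float, b: float):
    return lambda t: math.hypot(a * math.sin(t), b * math.cos(t))


def annulus_arc_length(a: float, b: float, theta_a: float, theta_b: float) -> float:
    """Arc length (cm) of the ellipse ``(a cos t, b sin t)`` over [theta_a, theta_b]."""
    if theta_a > theta_b:
        raise ValueError(f"need theta_a <= theta_b, got ({theta_a}, {theta_b})")
    if theta_a == theta_b:
        return 0.0
    value, _ = quad(_arc_element(a, b), theta_a, theta_b, epsrel=_QUAD_RTOL, limit=200)
    return float(value)


def _patch_band_integrals(params: ValveParameters) -> dict[str, float]:
    """Analytic area of each patch: h * integral of (upper-lower) ds."""
    ann, dims, part = params.annulus, params.dims, params.partition
    ds_ant = _arc_element(ann.a, ann.sl_ant)
    ds_post = _arc_element(ann.a, ann.sl_post)

    def integrate(f, lo, hi):
        v, _ = quad(f, lo, hi, epsrel=_QUAD_RTOL, limit=200)
        return float(v)

    return {
        "anterior": dims.h_ant
        * integrate(lambda t: math.sin(t) * ds_ant(t), 0.0, math.pi),
        "P1": dims.h_p1
        * integrate(
            lambda t: math.sin(part.c1 * (t - math.pi)) * ds_post(t), math.pi, part.theta1
        ),
        "P2": dims.h_p2
        * integrate(
            lambda t: (1.0 - part.delta)
            * math.sin(part.c2 * (t - part.theta1))
            * ds_post(t),
            part.theta1,
            part.theta2,
        ),
        "P3": dims.h_p3
        * integrate(
            lambda t: math.sin(part.c3 * (2.0 * math.pi - t)) * ds_post(t),
            part.theta2,
            2.0 * math.pi,
        ),
    }


def surface_area(obj: TriangleMesh | ValveParameters, patch: str | None = None) -> float:
    """Leaflet surface area, cm^2.

    For a mesh, sums triangle areas (optionally of one labelled patch).
    For model parameters, integrates band height times the ellipse arc
    element — exact up to quadrature tolerance because the cylindrical
    patches are developable.
    """
    if isinstance(obj, TriangleMesh):
        if patch is None:
            return obj.area()
        return obj.patch(patch).area()
    integrals = _patch_band_integrals(obj)
    if patch is None:
        return sum(integrals.values())
    return integrals[patch]


def validate_against_reference(
    params: ValveParameters,
    ranges: dict[str, dict[str, tuple[float, float, float]]] | None = None,
) -> MeasurementReport:
    """Measure the model and check it against the published cohort ranges.

    Reports each region's maximum height and nominal width against its
    reference range, the annulus diameters, and — side by side with the
    nominal widths — the arc widths the model actually realises on the
    annulus (proportional angular partitioning does not preserve arc
    length exactly).
    """
    ranges = REFERENCE_RANGES if ranges is None else ranges
    ann, dims, part = params.annulus, params.dims, params.partition
    entries: list[Measurement] = []

    widths = {"anterior": dims.w_ant, "P1": dims.w_p1, "P2": dims.w_p2, "P3": dims.w_p3}
    for region in ("anterior", "P1", "P2", "P3"):
        _, h_lo, h_hi = ranges[region]["height"]
        entries.append(
            Measurement(
                f"height_{region}",
                leaflet_max_height(params, region),  # type: ignore[arg-type]
                "cm",
                h_lo,
                h_hi,
                REFERENCE_SOURCE,
            )
        )
        _, w_lo, w_hi = ranges[region]["width"]
        entries.append(
            Measurement(f"width_{region}", widths[region], "cm", w_lo, w_hi, REFERENCE_SOURCE)
        )

    entries.append(Measurement("ic_diameter", ann.ic, "cm"))
    entries.append(Measurement("septolateral_diameter", ann.septolateral_diameter, "cm"))

    # realised arc widths on the annulus, for comparison with the nominal widths
    entries.append(
        Measurement(
            "arc_width_anterior", annulus_arc_length(ann.a, ann.sl_ant, 0.0, math.pi), "cm"
        )
    )
    for region, (lo, hi) in (
        ("P1", (math.pi, part.theta1)),
        ("P2", (part.theta1, part.theta2)),
        ("P3", (part.theta2, 2.0 * math.pi)),
    ):
        entries.append(
            Measurement(
                f"arc_width_{region}", annulus_arc_length(ann.a, ann.sl_post, lo, hi), "cm"
            )
        )
    return MeasurementReport(entries)
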