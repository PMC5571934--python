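"""Triangulation of the leaflet parameter domains and valve assembly.

Each leaflet patch has a non-rectangular parameter domain bounded below
and above by functions of the annulus angle.  The domain is sampled on
a structured grid that is *normalised across the band*: at angle
``y1`` the height samples are ``y2 = lower + v*(upper - lower)`` for
``v`` on ``n_v`` uniform levels.  Columns where the band collapses to a
point (the commissures, the P2 junction columns) degenerate to a single
vertex; triangles with vanishing area are culled after welding.

The grids always include the interval endpoints and the interior
maximum of each free edge (and the angle ``3*pi/2`` on the posterior
side), so axis extents and maximum heights of the meshed surface are
attained exactly rather than approximately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .valve_model import InvalidParameterError, PosteriorPartition, ValveParameters

__all__ = [
    "MeshResolution",
    "TriangleMesh",
    "MeshReport",
    "mesh_patch",
    "mesh_anterior",
    "mesh_scallop",
    "mesh_valve",
    "validate_mesh",
    "weld_vertices",
]

WELD_TOL = 1e-9  # cm
DEGENERATE_AREA_TOL = 1e-12  # cm^2


@dataclass(frozen=True)
class MeshResolution:
    """Samples along the annulus angle (``n_u``) and across the band (``n_v``)."""

    n_u: int = 200
    n_v: int = 50

    def __post_init__(self) -> None:
        if self.n_u < 2 or self.n_v < 2:
            raise InvalidParameterError(
                f"mesh resolution must be at least 2x2, got {self.n_u}x{self.n_v}"
            )


@dataclass
class TriangleMesh:
    """A labelled triangle surface mesh (vertices in cm)."""

    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray  # (m, 3) int64
    face_labels: np.ndarray = field(default=None)  # (m,) str patch labels

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.face_labels is None:
            self.face_labels = np.full(len(self.faces), "", dtype=object)
        else:
            self.face_labels = np.asarray(self.face_labels, dtype=object)
        if len(self.faces) and self.faces.max(initial=-1) >= len(self.vertices):
            raise InvalidParameterError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def area(self) -> float:
        """Total surface area, cm^2."""
        return float(self.face_areas().sum())

    def patch(self, label: str) -> "TriangleMesh":
        """Sub-mesh of the faces carrying ``label`` (vertices re-indexed)."""
        mask = self.face_labels == label
        faces = self.faces[mask]
        used = np.unique(faces)
        remap = np.full(self.n_vertices, -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        return TriangleMesh(self.vertices[used], remap[faces], self.face_labels[mask])

    def vertices_of(self, label: str) -> np.ndarray:
        """Vertex coordinates used by faces with ``label``."""
        used = np.unique(self.faces[self.face_labels == label])
        return self.vertices[used]


def weld_vertices(mesh: TriangleMesh, tol: float = WELD_TOL) -> TriangleMesh:
    """Merge coincident vertices (within ``tol``) and drop degenerate faces.

    Welding is idempotent: applying it twice changes nothing.
    """
    keys = np.round(mesh.vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)  # keep original vertex order for determinism
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    vertices = mesh.vertices[first[order]]
    faces = rank[inverse][mesh.faces]
    return _cull_degenerate(TriangleMesh(vertices, faces, mesh.face_labels))


def _cull_degenerate(mesh: TriangleMesh) -> TriangleMesh:
    keep = mesh.face_areas() > DEGENERATE_AREA_TOL
    return TriangleMesh(mesh.vertices, mesh.faces[keep], mesh.face_labels[keep])


def _grid_angles(lo: float, hi: float, n_u: int, forced: Sequence[float]) -> np.ndarray:
    y1 = np.linspace(lo, hi, n_u)
    extra = [t for t in forced if lo < t < hi]
    if extra:
        y1 = np.concatenate([y1, extra])
    y1 = np.unique(y1)
    # drop near-duplicates that differ only by float noise
    keep = np.concatenate([[True], np.diff(y1) > 1e-12])
    return y1[keep]


def mesh_patch(
    point_fn: Callable[[float, float], tuple[float, float, float]],
    y1_range: tuple[float, float],
    bounds_fn: Callable[[float], tuple[float, float]],
    res: MeshResolution,
    label: str = "",
    forced_y1: Sequence[float] = (),
) -> TriangleMesh:
    """Triangulate one leaflet patch on a band-normalised structured grid.

    ``point_fn(y1, y2)`` maps parameter coordinates to a surface point;
    ``bounds_fn(y1)`` returns the band ``(lower, upper)`` with
    ``upper >= lower``.  Collapsed columns produce single vertices and
    their zero-area triangles are removed.  Face winding is oriented so
    normals point away from the cylinder (z) axis.
    """
    y1s = _grid_angles(y1_range[0], y1_range[1], res.n_u, forced_y1)
    n_u, n_v = len(y1s), res.n_v
    v_levels = np.linspace(0.0, 1.0, n_v)

    verts = np.empty((n_u, n_v, 3))
    for i, y1 in enumerate(y1s):
        lower, upper = bounds_fn(y1)
        if upper < lower - 1e-12:
            raise InvalidParameterError(f"upper bound below lower bound at y1={y1}")
        for j, v in enumerate(v_levels):
            verts[i, j] = point_fn(y1, lower + v * (upper - lower))

    idx = np.arange(n_u * n_v).reshape(n_u, n_v)
    quads = np.stack(
        [
            idx[:-1, :-1].ravel(),
            idx[1:, :-1].ravel(),
            idx[1:, 1:].ravel(),
            idx[:-1, 1:].ravel(),
        ],
        axis=1,
    )
    faces = np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]])

    mesh = TriangleMesh(verts.reshape(-1, 3), faces, np.full(len(faces), label, dtype=object))
    mesh = weld_vertices(mesh)
    return _orient_outward(mesh)


def _orient_outward(mesh: TriangleMesh) -> TriangleMesh:
    """Flip winding if face normals point toward the cylinder (z) axis."""
    if not mesh.n_faces:
        return mesh
    v = mesh.vertices
    f = mesh.faces
    normals = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    centroids = v[f].mean(axis=1)
    radial = centroids.copy()
    radial[:, 2] = 0.0
    if float(np.einsum("ij,ij->", normals, radial)) < 0.0:
        f = f[:, [0, 2, 1]]
    return TriangleMesh(v, f, mesh.face_labels)


def mesh_anterior(params: ValveParameters, res: MeshResolution) -> TriangleMesh:
    """Mesh of the anterior leaflet patch."""
    ann, dims = params.annulus, params.dims

    def point(y1: float, y2: float) -> tuple[float, float, float]:
        return (ann.a * math.cos(y1), ann.sl_ant * math.sin(y1), dims.h_ant * y2)

    return mesh_patch(
        point,
        (0.0, math.pi),
        lambda y1: (0.0, math.sin(y1)),
        res,
        label="anterior",
        forced_y1=(math.pi / 2.0,),
    )


def _scallop_forced_points(partition: PosteriorPartition, scallop: str) -> tuple[float, ...]:
    lo, hi = partition.interval(scallop)
    c = {"P1": partition.c1, "P2": partition.c2, "P3": partition.c3}[scallop]
    if scallop == "P3":
        peak = 2.0 * math.pi - (math.pi / 2.0) / c
    else:
        peak = lo + (math.pi / 2.0) / c
    forced = [peak, 1.5 * math.pi]  # free-edge maximum; posterior ellipse apex
    return tuple(t for t in forced if lo < t < hi)


def mesh_scallop(params: ValveParameters, scallop: str, res: MeshResolution) -> TriangleMesh:
    """Mesh of one posterior scallop (``"P1"``, ``"P2"`` or ``"P3"``)."""
    ann, dims = params.annulus, params.dims
    partition = params.partition
    h = dims.height(scallop)  # type: ignore[arg-type]

    def point(y1: float, y2: float) -> tuple[float, float, float]:
        return (ann.a * math.cos(y1), ann.sl_post * math.sin(y1), h * y2)

    lo, hi = partition.interval(scallop)  # type: ignore[arg-type]

    def bounds_in_scallop(y1: float) -> tuple[float, float]:
        # evaluate this scallop's own bound even at the shared junction angle
        y1c = min(max(y1, lo), hi)
        if scallop == "P1":
            return 0.0, max(0.0, math.sin(partition.c1 * (y1c - math.pi)))
        if scallop == "P2":
            d = partition.delta
            return d, d + max(0.0, (1.0 - d) * math.sin(partition.c2 * (y1c - partition.theta1)))
        return 0.0, max(0.0, math.sin(partition.c3 * (2.0 * math.pi - y1c)))

    return mesh_patch(
        point,
        (lo, hi),
        bounds_in_scallop,
        res,
        label=scallop,
        forced_y1=_scallop_forced_points(partition, scallop),
    )


def mesh_valve(params: ValveParameters, res: MeshResolution | None = None) -> TriangleMesh:
    """Coupled full-valve mesh: anterior patch plus the three scallops.

    The two cylinders interface because the anterior ellipse's major
    axis equals the posterior ellipse's minor axis (both IC/2); the
    patches share the commissure points ``(+-IC/2, 0, 0)`` and the
    scallop junction columns, which are welded into single vertices.
    """
    res = res or MeshResolution()
    parts = [mesh_anterior(params, res)] + [
        mesh_scallop(params, s, res) for s in ("P1", "P2", "P3")
    ]
    offset = 0
    all_v, all_f, all_l = [], [], []
    for m in parts:
        all_v.append(m.vertices)
        all_f.append(m.faces + offset)
        all_l.append(m.face_labels)
        offset += m.n_vertices
    merged = TriangleMesh(np.vstack(all_v), np.vstack(all_f), np.concatenate(all_l))
    return weld_vertices(merged)


@dataclass(frozen=True)
class MeshReport:
    """Summary statistics and validity flags for a triangle mesh."""

    n_vertices: int
    n_faces: int
    n_degenerate: int
    n_duplicate_faces: int
    n_components: int
    min_edge_length: float
    max_edge_length: float
    patch_areas: dict
    is_valid: bool


def validate_mesh(mesh: TriangleMesh) -> MeshReport:
    """Check a mesh for degenerate faces, duplicates and connectivity."""
    if mesh.n_faces == 0 or mesh.n_vertices == 0:
        return MeshReport(
            n_vertices=mesh.n_vertices,
            n_faces=0,
            n_degenerate=0,
            n_duplicate_faces=0,
            n_components=0,
            min_edge_length=math.nan,
            max_edge_length=math.nan,
            patch_areas={},
            is_valid=False,
        )
    areas = mesh.face_areas()
    n_degenerate = int((areas <= DEGENERATE_AREA_TOL).sum())

    sorted_faces = np.sort(mesh.faces, axis=1)
    _, counts = np.unique(sorted_faces, axis=0, return_counts=True)
    n_duplicates = int((counts - 1).sum())

    edges = np.concatenate(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
    )
    lengths = np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1)

    graph = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
        shape=(mesh.n_vertices, mesh.n_vertices),
    )
    n_components, comp = connected_components(graph, directed=False)
    # count only components that carry faces (isolated vertices are welding artefacts)
    n_components = len(np.unique(comp[np.unique(mesh.faces)]))

    patch_areas = {
        str(label): float(areas[mesh.face_labels == label].sum())
        for label in np.unique(mesh.face_labels)
    }
    finite = bool(np.isfinite(mesh.vertices).all())
    return MeshReport(
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        n_degenerate=n_degenerate,
        n_duplicate_faces=n_duplicates,
        n_components=int(n_components),
        min_edge_length=float(lengths.min()),
        max_edge_length=float(lengths.max()),
        patch_areas=patch_areas,
        is_valid=finite and n_degenerate == 0 and n_duplicates == 0,
    )
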