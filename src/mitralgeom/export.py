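"""Mesh export to standard surface formats (STL, OBJ, PLY) via trimesh.

Lengths are written in centimetres, the model's native unit; pass
``scale_to_mm=True`` to emit millimetres for 3D-printing toolchains —
scaling is never implicit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import trimesh

from .meshing import TriangleMesh

__all__ = ["export_mesh", "load_mesh", "FORMATS"]

#: Supported export formats mapped to trimesh export types.
FORMATS = {
    "stl": "stl",  # binary
    "stl_ascii": "stl_ascii",
    "obj": "obj",
    "ply": "ply",
}

_SUFFIX_DEFAULT = {".stl": "stl", ".obj": "obj", ".ply": "ply"}


def _to_trimesh(mesh: TriangleMesh, scale: float = 1.0) -> trimesh.Trimesh:
    return trimesh.Trimesh(
        vertices=mesh.vertices * scale, faces=mesh.faces, process=False
    )


def export_mesh(
    mesh: TriangleMesh,
    path: str | Path,
    fmt: str | None = None,
    scale_to_mm: bool = False,
) -> Path:
    """Write ``mesh`` to ``path``; format inferred from the suffix if omitted.

    OBJ and PLY preserve vertex indices on re-import; STL stores
    per-triangle corners, so welding is lost (standard for the format).
    """
    if mesh.n_faces == 0 or mesh.n_vertices == 0:
        raise ValueError("refusing to export an empty mesh")
    path = Path(path)
    if fmt is None:
        fmt = _SUFFIX_DEFAULT.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if fmt not in FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; choose from {sorted(FORMATS)}")
    path.parent.mkdir(parents=True, exist_ok=True)
    tm = _to_trimesh(mesh, 10.0 if scale_to_mm else 1.0)
    if fmt == "stl_ascii":
        data = trimesh.exchange.stl.export_stl_ascii(tm)
        path.write_text(data)
    else:
        tm.export(str(path), file_type=FORMATS[fmt])
    return path


def load_mesh(path: str | Path) -> TriangleMesh:
    """Load a triangulated surface for measurement-only runs."""
    tm = trimesh.load_mesh(str(path), process=False)
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
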