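"""Minimal mesh/field writers: ASCII VTU for tet meshes, STL/PLY surfaces."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import trimesh

from .geometry import TetMesh, TriSurfaceMesh

__all__ = ["write_vtu", "write_surface", "read_surface"]

_VTK_TET4 = 10
_VTK_TET10 = 24


def _data_array(name: str, arr: np.ndarray) -> str:
    arr = np.asarray(arr)
    ncomp = 1 if arr.ndim == 1 else int(np.prod(arr.shape[1:]))
    flat = arr.reshape(arr.shape[0], -1)
    body = "\n".join(" ".join(f"{v:.10g}" for v in row) for row in flat)
    return (
        f'<DataArray type="Float64" Name="{name}" '
        f'NumberOfComponents="{ncomp}" format="ascii">\n{body}\n</DataArray>'
    )


def write_vtu(
    path,
    mesh: TetMesh,
    point_data: dict | None = None,
    cell_data: dict | None = None,
) -> None:
    """Write an unstructured-grid VTU file (ASCII) with optional fields.

    ``point_data`` arrays have leading dimension ``n_nodes``; ``cell_data``
    arrays have leading dimension ``n_elements`` (tensors are flattened
    row-major into 9 components).
    """
    nn, ne = mesh.n_nodes, mesh.n_elements
    npe = mesh.elements.shape[1]
    ctype = _VTK_TET10 if npe == 10 else _VTK_TET4

    pieces = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{nn}" NumberOfCells="{ne}">',
        "<Points>",
        _data_array("Points", mesh.nodes),
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        "\n".join(" ".join(map(str, row)) for row in mesh.elements),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(npe * (i + 1)) for i in range(ne)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join(str(ctype) for _ in range(ne)),
        "</DataArray>",
        "</Cells>",
    ]
    if point_data:
        pieces.append("<PointData>")
        for name, arr in point_data.items():
            pieces.append(_data_array(name, arr))
        pieces.append("</PointData>")
    if cell_data:
        pieces.append("<CellData>")
        for name, arr in cell_data.items():
            pieces.append(_data_array(name, arr))
        pieces.append("</CellData>")
    pieces += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(pieces))


def write_surface(path, surface: TriSurfaceMesh) -> None:
    """Write a surface mesh; format from the extension (.stl, .ply, .obj)."""
    surface.to_trimesh().export(str(path))


def read_surface(path) -> TriSurfaceMesh:
    mesh = trimesh.load(str(path), force="mesh")
    return TriSurfaceMesh(np.asarray(mesh.vertices, float), np.asarray(mesh.faces, np.int64))
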