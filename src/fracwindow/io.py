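"""Mesh and result writers: ASCII VTK-XML (VTU) and Abaqus input decks."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np

from .fem import TetMesh

VTK_TET = 10


def _fmt(arr: np.ndarray) -> str:
    a = np.asarray(arr)
    if np.issubdtype(a.dtype, np.integer):
        return " ".join(str(int(v)) for v in a.ravel())
    return " ".join(f"{float(v):.9g}" for v in a.ravel())


def write_vtu(
    path: str | Path,
    mesh: TetMesh,
    point_data: Mapping[str, np.ndarray] | None = None,
    cell_data: Mapping[str, np.ndarray] | None = None,
) -> None:
    """Write the mesh (plus optional fields) as an ASCII VTK unstructured grid."""
    n, m = mesh.n_nodes, mesh.n_elements
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "  <UnstructuredGrid>",
        f'    <Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "      <Points>",
        '        <DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        "          " + _fmt(mesh.nodes),
        "        </DataArray>",
        "      </Points>",
        "      <Cells>",
        '        <DataArray type="Int64" Name="connectivity" format="ascii">',
        "          " + _fmt(mesh.elements),
        "        </DataArray>",
        '        <DataArray type="Int64" Name="offsets" format="ascii">',
        "          " + _fmt(np.arange(1, m + 1) * 4),
        "        </DataArray>",
        '        <DataArray type="UInt8" Name="types" format="ascii">',
        "          " + _fmt(np.full(m, VTK_TET, dtype=np.uint8)),
        "        </DataArray>",
        "      </Cells>",
    ]

    def data_block(tag: str, data: Mapping[str, np.ndarray]) -> list[str]:
        block = [f"      <{tag}>"]
        for name, arr in data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            dtype = "Int64" if np.issubdtype(arr.dtype, np.integer) else "Float64"
            block += [
                f'        <DataArray type="{dtype}" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">',
                "          " + _fmt(arr),
                "        </DataArray>",
            ]
        block.append(f"      </{tag}>")
        return block

    if point_data:
        lines += data_block("PointData", point_data)
    if cell_data:
        lines += data_block("CellData", cell_data)
    lines += ["    </Piece>", "  </UnstructuredGrid>", "</VTKFile>", ""]
    Path(path).write_text("\n".join(lines))


def write_abaqus_inp(path: str | Path, mesh: TetMesh, deck_name: str = "fracwindow") -> None:
    """Export nodes, C3D4 elements and per-material element sets for
    cross-checking in external solvers."""
    if mesh.element_E is None:
        raise ValueError("mesh needs materials before export")
    lines = [f"*HEADING\n{deck_name}", "*NODE"]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i}, {x:.6g}, {y:.6g}, {z:.6g}")

    # group elements by (E, nu) so each group becomes one section
    key = np.round(np.column_stack([mesh.element_E, mesh.element_nu]), 9)
    uniq, inverse = np.unique(key, axis=0, return_inverse=True)
    lines.append("*ELEMENT, TYPE=C3D4")
    for e, conn in enumerate(mesh.elements, start=1):
        lines.append(f"{e}, " + ", ".join(str(int(c) + 1) for c in conn))
    for gi, (E, nu) in enumerate(uniq):
        ids = np.nonzero(inverse == gi)[0] + 1
        lines.append(f"*ELSET, ELSET=MAT{gi}")
        for chunk in np.array_split(ids, max(1, len(ids) // 12)):
            lines.append(", ".join(map(str, chunk)))
        lines += [
            f"*SOLID SECTION, ELSET=MAT{gi}, MATERIAL=MAT{gi}",
            f"*MATERIAL, NAME=MAT{gi}",
            "*ELASTIC",
            f"{E:.6g}, {nu:.6g}",
        ]
    Path(path).write_text("\n".join(lines) + "\n")
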