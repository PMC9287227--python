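"""Plain-text mesh and field I/O: ASCII VTU (XML UnstructuredGrid) and
Gmsh .msh v2.2 writers, plus a minimal .msh reader for round-tripping."""

from __future__ import annotations

import numpy as np

__all__ = ["write_vtu", "write_msh", "read_msh"]

_VTK_CELL = {8: 12, 20: 25}  # hexahedron, quadratic hexahedron

# VTK -> Gmsh node permutation for 20-node hexes
_VTK_TO_GMSH_HEX20 = np.array(
    [0, 1, 2, 3, 4, 5, 6, 7,          # corners coincide
     8, 11, 16, 9, 17, 10, 18, 19, 12, 15, 13, 14]
)


def _fmt_array(a: np.ndarray, per_line: int = 6) -> str:
    flat = np.asarray(a).ravel()
    if flat.dtype.kind in "iu":
        items = [str(int(v)) for v in flat]
    else:
        items = [f"{v:.10g}" for v in flat]
    lines = [
        " ".join(items[i : i + per_line]) for i in range(0, len(items), per_line)
    ]
    return "\n".join(lines)


def write_vtu(path, nodes, elems, order, point_data=None, cell_data=None):
    """Write an ASCII .vtu file with optional point/cell data arrays.

    Vector point data must have shape (n_nodes, 3); scalars (n,).
    """
    nodes = np.asarray(nodes)
    elems = np.asarray(elems)
    ctype = _VTK_CELL[elems.shape[1]]
    nn, ne = nodes.shape[0], elems.shape[0]
    parts = []
    w = parts.append
    w('<?xml version="1.0"?>')
    w('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">')
    w("<UnstructuredGrid>")
    w(f'<Piece NumberOfPoints="{nn}" NumberOfCells="{ne}">')
    w("<Points>")
    w('<DataArray type="Float64" NumberOfComponents="3" format="ascii">')
    w(_fmt_array(nodes))
    w("</DataArray>")
    w("</Points>")
    if point_data:
        w("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            typ = "Int32" if arr.dtype.kind in "iu" else "Float64"
            w(
                f'<DataArray type="{typ}" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
            )
            w(_fmt_array(arr))
            w("</DataArray>")
        w("</PointData>")
    if cell_data:
        w("<CellData>")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            typ = "Int32" if arr.dtype.kind in "iu" else "Float64"
            w(
                f'<DataArray type="{typ}" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
            )
            w(_fmt_array(arr))
            w("</DataArray>")
        w("</CellData>")
    w("<Cells>")
    w('<DataArray type="Int64" Name="connectivity" format="ascii">')
    w(_fmt_array(elems.astype(np.int64), per_line=elems.shape[1]))
    w("</DataArray>")
    w('<DataArray type="Int64" Name="offsets" format="ascii">')
    w(_fmt_array(np.arange(1, ne + 1, dtype=np.int64) * elems.shape[1], per_line=12))
    w("</DataArray>")
    w('<DataArray type="UInt8" Name="types" format="ascii">')
    w(_fmt_array(np.full(ne, ctype, dtype=np.int64), per_line=24))
    w("</DataArray>")
    w("</Cells>")
    w("</Piece>")
    w("</UnstructuredGrid>")
    w("</VTKFile>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts) + "\n")


def write_msh(path, mesh) -> None:
    """Write a ShellMesh as Gmsh .msh v2.2 ASCII; region tags become
    physical/elementary tags."""
    nodes, elems = mesh.nodes, mesh.elems
    nen = elems.shape[1]
    etype = 5 if nen == 8 else 17
    conn = elems if nen == 8 else elems[:, _VTK_TO_GMSH_HEX20]
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes",
             str(nodes.shape[0])]
    for i, p in enumerate(nodes, start=1):
        lines.append(f"{i} {p[0]:.10g} {p[1]:.10g} {p[2]:.10g}")
    lines += ["$EndNodes", "$Elements", str(elems.shape[0])]
    for e in range(elems.shape[0]):
        tag = int(mesh.region_id[e])
        node_list = " ".join(str(int(n) + 1) for n in conn[e])
        lines.append(f"{e + 1} {etype} 2 {tag} {tag} {node_list}")
    lines += ["$EndElements"]
    names = mesh.region_names
    lines += ["$PhysicalNames", str(len(names))]
    for rid in sorted(names):
        lines.append(f'3 {rid} "{names[rid]}"')
    lines += ["$EndPhysicalNames"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path):
    """Read nodes, connectivity (VTK ordering), region ids and names from a
    Gmsh v2.2 file written by :func:`write_msh`."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    i = lines.index("$Nodes")
    nn = int(lines[i + 1])
    nodes = np.array(
        [list(map(float, ln.split()[1:4])) for ln in lines[i + 2 : i + 2 + nn]]
    )
    j = lines.index("$Elements")
    ne = int(lines[j + 1])
    conn, rids = [], []
    for ln in lines[j + 2 : j + 2 + ne]:
        parts = ln.split()
        etype = int(parts[1])
        ntags = int(parts[2])
        rids.append(int(parts[3]))
        nodes_1b = np.array(parts[3 + ntags :], dtype=np.int64) - 1
        if etype == 17:
            inv = np.empty_like(_VTK_TO_GMSH_HEX20)
            inv[_VTK_TO_GMSH_HEX20] = np.arange(20)
            nodes_1b = nodes_1b[inv]
        conn.append(nodes_1b)
    elems = np.vstack(conn)
    names = {}
    if "$PhysicalNames" in lines:
        k = lines.index("$PhysicalNames")
        npn = int(lines[k + 1])
        for ln in lines[k + 2 : k + 2 + npn]:
            p = ln.split(maxsplit=2)
            names[int(p[1])] = p[2].strip('"')
    return nodes, elems, np.array(rids, dtype=np.int32), names
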