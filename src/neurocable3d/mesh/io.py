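"""Read/write labeled tetrahedral meshes as Gmsh MSH 4.1 or VTK .vtu (ASCII).

Subdomain, membrane-patch and cell labels round-trip through both formats:

* Gmsh: one discrete entity per (label, cell) combination, named through
  ``$PhysicalNames`` as ``volume:<subdomain>:<cell>`` for tetrahedra and
  ``surface:<patch>:<cell>`` for membrane triangles.  Membrane triangles are
  stored as oriented 2D elements alongside the tets.
* VTU: tets and membrane triangles in one unstructured grid with integer
  cell-data arrays ``subdomain``, ``cell_id`` and ``patch`` (-1 on tets).

Only the ASCII variants of both formats are supported; binary files are
rejected with a clear error.  :func:`write_vtu_fields` additionally exports
per-vertex solution snapshots for visualization.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .core import Mesh, Patch, Subdomain

__all__ = ["read_mesh", "write_mesh", "write_vtu_fields"]


def write_mesh(mesh: Mesh, path, fmt: str | None = None) -> None:
    """Write a mesh; format from ``fmt`` or the file suffix (.msh/.vtu)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt in ("msh", "gmsh"):
        _write_msh(mesh, path)
    elif fmt in ("vtu", "vtk"):
        _write_vtu(mesh, path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r} (use 'gmsh' or 'vtk')")


def read_mesh(path, fmt: str | None = None) -> Mesh:
    """Read a labeled mesh; rejects files without subdomain labels."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = fmt or path.suffix.lstrip(".")
    if fmt in ("msh", "gmsh"):
        return _read_msh(path)
    if fmt in ("vtu", "vtk"):
        return _read_vtu(path)
    raise ValueError(f"unknown mesh format {fmt!r} (use 'gmsh' or 'vtk')")


# ---------------------------------------------------------------------------
# Gmsh MSH 4.1 ASCII
# ---------------------------------------------------------------------------


def _label_groups(mesh: Mesh):
    """(dim, name, element array) per physical group, deterministic order."""
    groups = []
    for sub in np.unique(mesh.tet_subdomain):
        for cell in np.unique(mesh.tet_cell[mesh.tet_subdomain == sub]):
            sel = (mesh.tet_subdomain == sub) & (mesh.tet_cell == cell)
            name = f"volume:{Subdomain(sub).name}:{int(cell)}"
            groups.append((3, name, mesh.tets[sel]))
    for patch in np.unique(mesh.tri_patch):
        for cell in np.unique(mesh.tri_cell[mesh.tri_patch == patch]):
            sel = (mesh.tri_patch == patch) & (mesh.tri_cell == cell)
            name = f"surface:{Patch(patch).name}:{int(cell)}"
            groups.append((2, name, mesh.mem_tris[sel]))
    return groups


def _write_msh(mesh: Mesh, path: Path) -> None:
    groups = _label_groups(mesh)
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    lines += ["$PhysicalNames", str(len(groups))]
    for tag, (dim, name, _) in enumerate(groups, start=1):
        lines.append(f'{dim} {tag} "{name}"')
    lines.append("$EndPhysicalNames")

    surf = [(t, g) for t, g in enumerate(groups, start=1) if g[0] == 2]
    vol = [(t, g) for t, g in enumerate(groups, start=1) if g[0] == 3]
    lines += ["$Entities", f"0 0 {len(surf)} {len(vol)}"]
    for tag, (dim, name, _) in surf:
        lines.append(f"{tag} 0 0 0 0 0 0 1 {tag}")
    for tag, (dim, name, _) in vol:
        lines.append(f"{tag} 0 0 0 0 0 0 1 {tag} 0")
    lines.append("$EndEntities")

    nv = mesh.n_vertices
    first_vol_tag = vol[0][0] if vol else 1
    lines += ["$Nodes", f"1 {nv} 1 {nv}", f"3 {first_vol_tag} 0 {nv}"]
    lines += [str(i + 1) for i in range(nv)]
    lines += [
        f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.vertices
    ]
    lines.append("$EndNodes")

    n_elem = sum(len(g[2]) for g in groups)
    lines += ["$Elements", f"{len(groups)} {n_elem} 1 {n_elem}"]
    eid = 1
    for tag, (dim, name, elems) in enumerate(groups, start=1):
        etype = 4 if dim == 3 else 2  # 4-node tet / 3-node triangle
        lines.append(f"{dim} {tag} {etype} {len(elems)}")
        for el in elems:
            lines.append(f"{eid} " + " ".join(str(int(v) + 1) for v in el))
            eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def _read_msh(path: Path) -> Mesh:
    text = path.read_text(errors="replace")
    if "$MeshFormat" not in text:
        raise ValueError("not a Gmsh MSH file")
    sections = {}
    for block in text.split("$")[1:]:
        name, _, body = block.partition("\n")
        if not name.startswith("End"):
            sections[name.strip()] = body
    fmt = sections["MeshFormat"].split()
    if fmt[1] != "0":
        raise ValueError("binary MSH files are not supported; write ASCII")

    names = {}
    pn = sections.get("PhysicalNames", "0").strip().splitlines()
    for line in pn[1:]:
        dim, tag, name = line.split(maxsplit=2)
        names[(int(dim), int(tag))] = name.strip('"')

    # entity tag -> physical tag
    ent_phys = {}
    ent = sections["Entities"].strip().splitlines()
    counts = [int(c) for c in ent[0].split()]
    row = 1
    for dim, cnt in zip(range(4), counts):
        for _ in range(cnt):
            fields = ent[row].split()
            row += 1
            if dim == 0:
                tag, nphys_at = int(fields[0]), 4
            else:
                tag, nphys_at = int(fields[0]), 7
            nphys = int(fields[nphys_at])
            if nphys >= 1:
                ent_phys[(dim, tag)] = int(fields[nphys_at + 1])

    node_lines = sections["Nodes"].strip().splitlines()
    n_blocks, n_nodes = int(node_lines[0].split()[0]), int(node_lines[0].split()[1])
    coords = np.empty((n_nodes, 3))
    node_id = {}
    row = 1
    for _ in range(n_blocks):
        _, _, _, cnt = (int(v) for v in node_lines[row].split())
        row += 1
        tags = [int(node_lines[row + i]) for i in range(cnt)]
        row += cnt
        for i, tag in enumerate(tags):
            node_id[tag] = len(node_id)
            coords[node_id[tag]] = [float(v) for v in node_lines[row + i].split()[:3]]
        row += cnt

    elem_lines = sections["Elements"].strip().splitlines()
    n_blocks = int(elem_lines[0].split()[0])
    tets, tet_sub, tet_cell = [], [], []
    tris, tri_patch, tri_cell = [], [], []
    row = 1
    for _ in range(n_blocks):
        dim, etag, etype, cnt = (int(v) for v in elem_lines[row].split())
        row += 1
        phys = ent_phys.get((dim, etag))
        name = names.get((dim, phys), "")
        for i in range(cnt):
            fields = elem_lines[row + i].split()
            conn = [node_id[int(v)] for v in fields[1:]]
            if etype == 4:
                kind, label, cell = name.split(":")
                tets.append(conn)
                tet_sub.append(int(Subdomain[label]))
                tet_cell.append(int(cell))
            elif etype == 2:
                kind, label, cell = name.split(":")
                tris.append(conn)
                tri_patch.append(int(Patch[label]))
                tri_cell.append(int(cell))
        row += cnt
    if not tets:
        raise ValueError("mesh file contains no labeled tetrahedra (subdomain required)")

    return Mesh(
        vertices=coords,
        tets=np.asarray(tets, dtype=np.int64),
        tet_subdomain=np.asarray(tet_sub, dtype=np.int64),
        tet_cell=np.asarray(tet_cell, dtype=np.int64),
        mem_tris=np.asarray(tris, dtype=np.int64) if tris else np.zeros((0, 3), np.int64),
        tri_patch=np.asarray(tri_patch, dtype=np.int64),
        tri_cell=np.asarray(tri_cell, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# VTK unstructured grid (.vtu, ASCII XML)
# ---------------------------------------------------------------------------

_VTK_TET = 10
_VTK_TRI = 5


def _data_array(parent, name, values, dtype):
    da = ET.SubElement(
        parent,
        "DataArray",
        type=dtype,
        Name=name,
        format="ascii",
        NumberOfComponents=str(values.shape[1] if values.ndim == 2 else 1),
    )
    if values.ndim == 2:
        da.text = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in values)
    else:
        fmt = "{:.17g}" if "Float" in dtype else "{:d}"
        da.text = "\n".join(fmt.format(v) for v in values)
    return da


def _write_vtu(mesh: Mesh, path: Path, point_data: dict | None = None) -> None:
    n_cells = mesh.n_tets + len(mesh.mem_tris)
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1", byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(
        grid, "Piece", NumberOfPoints=str(mesh.n_vertices), NumberOfCells=str(n_cells)
    )
    pts = ET.SubElement(piece, "Points")
    _data_array(pts, "Points", mesh.vertices, "Float64")

    cells = ET.SubElement(piece, "Cells")
    conn = np.concatenate([mesh.tets.ravel(), mesh.mem_tris.ravel()])
    offsets = np.concatenate(
        [4 * (np.arange(mesh.n_tets) + 1), 4 * mesh.n_tets + 3 * (np.arange(len(mesh.mem_tris)) + 1)]
    )
    types = np.concatenate(
        [np.full(mesh.n_tets, _VTK_TET), np.full(len(mesh.mem_tris), _VTK_TRI)]
    )
    _data_array(cells, "connectivity", conn.astype(np.int64), "Int64")
    _data_array(cells, "offsets", offsets.astype(np.int64), "Int64")
    _data_array(cells, "types", types.astype(np.int64), "Int64")

    cd = ET.SubElement(piece, "CellData")
    sub = np.concatenate([mesh.tet_subdomain, np.full(len(mesh.mem_tris), -1)])
    cid = np.concatenate([mesh.tet_cell, mesh.tri_cell])
    patch = np.concatenate([np.full(mesh.n_tets, -1), mesh.tri_patch])
    _data_array(cd, "subdomain", sub.astype(np.int64), "Int64")
    _data_array(cd, "cell_id", cid.astype(np.int64), "Int64")
    _data_array(cd, "patch", patch.astype(np.int64), "Int64")

    if point_data:
        pd = ET.SubElement(piece, "PointData")
        for name, values in point_data.items():
            _data_array(pd, name, np.asarray(values, float), "Float64")

    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def write_vtu_fields(mesh: Mesh, path, point_data: dict) -> None:
    """Write a VTU snapshot with per-vertex solution fields (e.g. V_m,
    Phi_out expanded to the full vertex set)."""
    _write_vtu(mesh, Path(path), point_data=point_data)


def _read_vtu(path: Path) -> Mesh:
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    arrays = {}
    for da in piece.iter("DataArray"):
        if da.get("format") != "ascii":
            raise ValueError("binary VTU files are not supported; write ASCII")
        arrays[da.get("Name")] = da
    verts = np.fromstring(arrays["Points"].text.replace("\n", " "), sep=" ").reshape(-1, 3)
    conn = np.fromstring(arrays["connectivity"].text.replace("\n", " "), dtype=np.int64, sep=" ")
    offsets = np.fromstring(arrays["offsets"].text.replace("\n", " "), dtype=np.int64, sep=" ")
    types = np.fromstring(arrays["types"].text.replace("\n", " "), dtype=np.int64, sep=" ")
    if "subdomain" not in arrays:
        raise ValueError("VTU file lacks the 'subdomain' cell-data labels")
    sub = np.fromstring(arrays["subdomain"].text.replace("\n", " "), dtype=np.int64, sep=" ")
    cid = np.fromstring(arrays["cell_id"].text.replace("\n", " "), dtype=np.int64, sep=" ")
    patch = np.fromstring(arrays["patch"].text.replace("\n", " "), dtype=np.int64, sep=" ")

    starts = np.concatenate([[0], offsets[:-1]])
    tets, tet_sub, tet_cell = [], [], []
    tris, tri_patch, tri_cell = [], [], []
    for i, (s, e, t) in enumerate(zip(starts, offsets, types)):
        if t == _VTK_TET:
            tets.append(conn[s:e])
            tet_sub.append(sub[i])
            tet_cell.append(cid[i])
        elif t == _VTK_TRI:
            tris.append(conn[s:e])
            tri_patch.append(patch[i])
            tri_cell.append(cid[i])
    if not tets:
        raise ValueError("VTU file contains no labeled tetrahedra (subdomain required)")
    return Mesh(
        vertices=verts,
        tets=np.asarray(tets, dtype=np.int64),
        tet_subdomain=np.asarray(tet_sub, dtype=np.int64),
        tet_cell=np.asarray(tet_cell, dtype=np.int64),
        mem_tris=np.asarray(tris, dtype=np.int64) if tris else np.zeros((0, 3), np.int64),
        tri_patch=np.asarray(tri_patch, dtype=np.int64),
        tri_cell=np.asarray(tri_cell, dtype=np.int64),
    )
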