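"""Labeled tetrahedral meshes with an explicit membrane surface.

A :class:`Mesh` discretizes a bounded piece of space split into an
intracellular region (one or more cells) and the surrounding extracellular
region.  The membrane is the set of triangular faces shared by exactly one
intracellular and one extracellular tetrahedron; each membrane triangle
carries a patch label (dendrite, active membrane, myelin, synapse, stimulus)
and the id of the cell it belongs to.  Patch labels encode where each term of
the total transmembrane current applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "Subdomain",
    "Patch",
    "Mesh",
    "tet_volumes",
    "triangle_area_vectors",
    "extract_membrane",
    "refine_uniform",
]


class Subdomain(IntEnum):
    """Volume subdomain labels."""

    INTRA = 1
    EXTRA = 2


class Patch(IntEnum):
    """Membrane-surface patch labels (the regional delta functions)."""

    DENDRITE = 0
    ACTIVE = 1
    MYELIN = 2
    SYNAPSE_PRE = 3
    SYNAPSE_POST = 4
    STIMULUS = 5


def tet_volumes(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for right-handed ordering)."""
    a = vertices[tets[:, 1]] - vertices[tets[:, 0]]
    b = vertices[tets[:, 2]] - vertices[tets[:, 0]]
    c = vertices[tets[:, 3]] - vertices[tets[:, 0]]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


def triangle_area_vectors(vertices: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Area-weighted normals 0.5 * (v1-v0) x (v2-v0) of oriented triangles."""
    a = vertices[tris[:, 1]] - vertices[tris[:, 0]]
    b = vertices[tris[:, 2]] - vertices[tris[:, 0]]
    return 0.5 * np.cross(a, b)


@dataclass
class Mesh:
    """Tetrahedral mesh with subdomain, membrane-patch and cell labels.

    Attributes
    ----------
    vertices : (nv, 3) float array, coordinates in um.
    tets : (nt, 4) int array, vertex indices (positive orientation).
    tet_subdomain : (nt,) int array of :class:`Subdomain` values.
    tet_cell : (nt,) int array; cell id for INTRA tets, -1 for EXTRA.
    mem_tris : (nm, 3) int array; oriented so the normal points from the
        intracellular to the extracellular side.
    tri_patch : (nm,) int array of :class:`Patch` values.
    tri_cell : (nm,) int array, cell id of each membrane triangle.
    markers : optional named probe vertices (name -> vertex index).
    """

    vertices: np.ndarray
    tets: np.ndarray
    tet_subdomain: np.ndarray
    tet_cell: np.ndarray
    mem_tris: np.ndarray
    tri_patch: np.ndarray
    tri_cell: np.ndarray
    markers: dict = field(default_factory=dict)

    # -- basic derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def n_cells(self) -> int:
        intra = self.tet_cell[self.tet_subdomain == Subdomain.INTRA]
        return 0 if len(intra) == 0 else int(intra.max()) + 1

    def subdomain_volume(self, subdomain: Subdomain) -> float:
        mask = self.tet_subdomain == subdomain
        return float(tet_volumes(self.vertices, self.tets[mask]).sum())

    def membrane_area(self) -> float:
        return float(
            np.linalg.norm(
                triangle_area_vectors(self.vertices, self.mem_tris), axis=1
            ).sum()
        )

    def subdomain_vertices(self, subdomain: Subdomain) -> np.ndarray:
        """Sorted unique vertex indices referenced by tets of a subdomain."""
        return np.unique(self.tets[self.tet_subdomain == subdomain])

    def membrane_vertices(self) -> np.ndarray:
        return np.unique(self.mem_tris)

    def nearest_vertex(self, point) -> int:
        d = np.linalg.norm(self.vertices - np.asarray(point, float), axis=1)
        return int(np.argmin(d))

    # -- validation ---------------------------------------------------------------

    def validate(self, tol: float = 1e-12) -> None:
        """Check structural invariants; raise ``ValueError`` on violation.

        Checks: index ranges, non-degenerate positively oriented tets, every
        membrane triangle shared by exactly one INTRA and one EXTRA tet, and
        membrane orientation pointing from intra to extra.
        """
        if self.tets.size and self.tets.max() >= self.n_vertices:
            raise ValueError("tetrahedron references a non-existent vertex")
        vols = tet_volumes(self.vertices, self.tets)
        scale = np.abs(vols).max() if len(vols) else 1.0
        bad = np.nonzero(vols <= tol * scale)[0]
        if len(bad):
            raise ValueError(
                f"degenerate or inverted tetrahedra at indices {bad[:10].tolist()}"
            )
        if len(self.tet_subdomain) != self.n_tets or len(self.tet_cell) != self.n_tets:
            raise ValueError("per-tet label arrays must match the tet count")
        if len(self.mem_tris) != len(self.tri_patch) or len(self.mem_tris) != len(
            self.tri_cell
        ):
            raise ValueError("per-triangle label arrays must match the triangle count")

        # Each membrane triangle must separate exactly one INTRA and one EXTRA tet.
        face_map = _tet_face_map(self.tets)
        intra_bary = {}
        for i, tri in enumerate(self.mem_tris):
            key = tuple(sorted(int(v) for v in tri))
            owners = face_map.get(key)
            if owners is None or len(owners) != 2:
                raise ValueError(f"membrane triangle {i} is not an interior face")
            subs = {int(self.tet_subdomain[t]) for t in owners}
            if subs != {int(Subdomain.INTRA), int(Subdomain.EXTRA)}:
                raise ValueError(
                    f"membrane triangle {i} does not separate INTRA from EXTRA"
                )
            t_in = next(
                t for t in owners if self.tet_subdomain[t] == Subdomain.INTRA
            )
            intra_bary[i] = self.vertices[self.tets[t_in]].mean(axis=0)

        normals = triangle_area_vectors(self.vertices, self.mem_tris)
        centers = self.vertices[self.mem_tris].mean(axis=1)
        for i in range(len(self.mem_tris)):
            if np.dot(normals[i], centers[i] - intra_bary[i]) <= 0:
                raise ValueError(
                    f"membrane triangle {i} is oriented extra->intra (expected intra->extra)"
                )


def _tet_face_map(tets: np.ndarray) -> dict:
    """Map sorted face -> list of owning tet indices."""
    faces = {}
    local = ((1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2))
    for t, tet in enumerate(tets):
        for lf in local:
            key = tuple(sorted(int(tet[i]) for i in lf))
            faces.setdefault(key, []).append(t)
    return faces


def extract_membrane(
    vertices: np.ndarray,
    tets: np.ndarray,
    tet_subdomain: np.ndarray,
    tet_cell: np.ndarray,
):
    """Find all faces shared by an INTRA and an EXTRA tet, oriented intra->extra.

    Returns ``(mem_tris, tri_cell)`` where ``tri_cell`` is the cell id of the
    intracellular owner.  Patch labels are left to the caller (builders
    classify by position).
    """
    face_map = _tet_face_map(tets)
    tris = []
    cells = []
    for key, owners in face_map.items():
        if len(owners) != 2:
            continue
        s0, s1 = int(tet_subdomain[owners[0]]), int(tet_subdomain[owners[1]])
        if {s0, s1} != {int(Subdomain.INTRA), int(Subdomain.EXTRA)}:
            continue
        t_in = owners[0] if s0 == int(Subdomain.INTRA) else owners[1]
        tri = np.array(key, dtype=np.int64)
        # orient: normal away from the intra tet barycenter
        bary = vertices[tets[t_in]].mean(axis=0)
        n = np.cross(
            vertices[tri[1]] - vertices[tri[0]], vertices[tri[2]] - vertices[tri[0]]
        )
        center = vertices[tri].mean(axis=0)
        if np.dot(n, center - bary) < 0:
            tri = tri[[0, 2, 1]]
        tris.append(tri)
        cells.append(int(tet_cell[t_in]))
    if tris:
        order = np.lexsort(np.array(tris).T[::-1])
        return np.array(tris, dtype=np.int64)[order], np.array(cells, dtype=np.int64)[order]
    return np.zeros((0, 3), dtype=np.int64), np.zeros(0, dtype=np.int64)


# -- uniform (red) refinement -----------------------------------------------------

_TET_EDGES = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def refine_uniform(mesh: Mesh) -> Mesh:
    """Uniform red refinement: each tet into 8 children, each membrane
    triangle into 4, via edge midpoints (Bey's scheme, diagonal m02-m13).

    Total volume and total membrane area are preserved exactly; labels are
    inherited from the parents.
    """
    verts = mesh.vertices
    edge_mid: dict[tuple[int, int], int] = {}
    new_verts = [verts]
    next_id = len(verts)

    def midpoint(a: int, b: int) -> int:
        nonlocal next_id
        key = (a, b) if a < b else (b, a)
        idx = edge_mid.get(key)
        if idx is None:
            edge_mid[key] = idx = next_id
            next_id += 1
            new_verts.append(0.5 * (verts[key[0]] + verts[key[1]])[None, :])
        return idx

    child_tets = []
    child_sub = []
    child_cell = []
    for t, tet in enumerate(mesh.tets):
        v0, v1, v2, v3 = (int(v) for v in tet)
        m01 = midpoint(v0, v1)
        m02 = midpoint(v0, v2)
        m03 = midpoint(v0, v3)
        m12 = midpoint(v1, v2)
        m13 = midpoint(v1, v3)
        m23 = midpoint(v2, v3)
        children = (
            (v0, m01, m02, m03),
            (m01, v1, m12, m13),
            (m02, m12, v2, m23),
            (m03, m13, m23, v3),
            (m01, m02, m03, m13),
            (m01, m02, m13, m12),
            (m02, m03, m13, m23),
            (m02, m12, m13, m23),
        )
        child_tets.extend(children)
        child_sub.extend([mesh.tet_subdomain[t]] * 8)
        child_cell.extend([mesh.tet_cell[t]] * 8)

    child_tris = []
    child_patch = []
    child_tricell = []
    for i, tri in enumerate(mesh.mem_tris):
        v0, v1, v2 = (int(v) for v in tri)
        m01 = midpoint(v0, v1)
        m12 = midpoint(v1, v2)
        m02 = midpoint(v0, v2)
        for child in ((v0, m01, m02), (m01, v1, m12), (m02, m12, v2), (m01, m12, m02)):
            child_tris.append(child)
            child_patch.append(mesh.tri_patch[i])
            child_tricell.append(mesh.tri_cell[i])

    vertices = np.vstack(new_verts)
    tets = np.array(child_tets, dtype=np.int64)
    # restore positive orientation where the child ordering flipped it
    vols = tet_volumes(vertices, tets)
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]

    return Mesh(
        vertices=vertices,
        tets=tets,
        tet_subdomain=np.array(child_sub, dtype=np.int64),
        tet_cell=np.array(child_cell, dtype=np.int64),
        mem_tris=np.array(child_tris, dtype=np.int64)
        if child_tris
        else np.zeros((0, 3), dtype=np.int64),
        tri_patch=np.array(child_patch, dtype=np.int64),
        tri_cell=np.array(child_tricell, dtype=np.int64),
        markers=dict(mesh.markers),
    )
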