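"""Barycentric (box-method) dual grid for vertex-centered finite volumes.

Each tetrahedron is subdivided by connecting its edge midpoints, face
barycenters and its own barycenter; the piece around each of the four
vertices is that vertex's sub-control-volume in the tet (exactly 1/4 of the
tet volume for the barycentric construction).  For every tet edge (k, j) the
dual face separating the sub-volumes of k and j inside the tet is the
non-planar quadrilateral [edge midpoint, face barycenter, tet barycenter,
other face barycenter]; its *integrated* normal (which is all the flux
operator needs, and which depends only on the quad's boundary contour) is
stored per tet and per edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Mesh, Patch, Subdomain, tet_volumes, triangle_area_vectors

__all__ = ["DualGrid", "build_dual_grid", "TET_EDGE_PAIRS"]

#: Local vertex index pairs of the six tet edges, in storage order.
TET_EDGE_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass
class DualGrid:
    """Pre-integrated dual-grid quantities of a labeled mesh.

    Attributes
    ----------
    volumes : dict Subdomain -> (nv,) array; control-volume share of each
        global vertex restricted to that subdomain (um^3).
    subface_normals : (nt, 6, 3) array; integrated area-weighted normal of
        the dual face of each tet edge, oriented from the lower to the higher
        *local* vertex index of :data:`TET_EDGE_PAIRS` (um^2).
    membrane_area : dict Patch -> (nv,) array; area of the membrane surface
        associated with each vertex, per patch label (um^2).
    membrane_area_total : (nv,) array; sum over patches.
    membrane_normal : (nv, 3) array; integrated intra->extra membrane normal
        per vertex (um^2).
    cell_of_vertex : (nv,) int array; owning cell for membrane vertices,
        -1 elsewhere.
    """

    volumes: dict
    subface_normals: np.ndarray
    membrane_area: dict
    membrane_area_total: np.ndarray
    membrane_normal: np.ndarray
    cell_of_vertex: np.ndarray


def build_dual_grid(mesh: Mesh) -> DualGrid:
    """Construct the barycentric dual grid of a validated mesh.

    Raises ``ValueError`` with the offending index for degenerate tets.
    """
    verts = mesh.vertices
    tets = mesh.tets
    nv = mesh.n_vertices

    vols = tet_volumes(verts, tets)
    scale = np.abs(vols).max() if len(vols) else 1.0
    bad = np.nonzero(vols <= 1e-14 * scale)[0]
    if len(bad):
        raise ValueError(f"degenerate tetrahedron at index {int(bad[0])}")

    volumes = {}
    for sub in (Subdomain.INTRA, Subdomain.EXTRA):
        acc = np.zeros(nv)
        mask = mesh.tet_subdomain == sub
        # barycentric dual: each vertex of a tet owns exactly V/4
        np.add.at(acc, tets[mask].ravel(), np.repeat(vols[mask] / 4.0, 4))
        volumes[sub] = acc

    subface_normals = _subface_normals(verts, tets)

    # membrane areas per vertex per patch; each triangle contributes A/3 to
    # each of its vertices (barycentric dual of the surface triangulation)
    area_vecs = triangle_area_vectors(verts, mesh.mem_tris)
    areas = np.linalg.norm(area_vecs, axis=1)
    membrane_area = {}
    for patch in Patch:
        acc = np.zeros(nv)
        mask = mesh.tri_patch == patch
        if mask.any():
            np.add.at(acc, mesh.mem_tris[mask].ravel(), np.repeat(areas[mask] / 3.0, 3))
        membrane_area[patch] = acc
    membrane_area_total = sum(membrane_area.values(), np.zeros(nv))

    membrane_normal = np.zeros((nv, 3))
    np.add.at(
        membrane_normal,
        mesh.mem_tris.ravel(),
        np.repeat(area_vecs / 3.0, 3, axis=0),
    )

    cell_of_vertex = np.full(nv, -1, dtype=np.int64)
    for i, tri in enumerate(mesh.mem_tris):
        cell_of_vertex[tri] = mesh.tri_cell[i]

    return DualGrid(
        volumes=volumes,
        subface_normals=subface_normals,
        membrane_area=membrane_area,
        membrane_area_total=membrane_area_total,
        membrane_normal=membrane_normal,
        cell_of_vertex=cell_of_vertex,
    )


def _subface_normals(verts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Integrated dual-face normals per tet edge (vectorized).

    For edge (a, b) the dual face is the quad [M, F1, C, F2] with M the edge
    midpoint, F1/F2 the barycenters of the two faces containing the edge and
    C the tet barycenter.  The integrated normal is the sum of the two
    triangle area vectors of any triangulation of the quad; it is oriented
    from local vertex a to local vertex b.
    """
    x = verts[tets]  # (nt, 4, 3)
    c = x.mean(axis=1)  # tet barycenters
    nt = len(tets)
    normals = np.zeros((nt, 6, 3))
    # face barycenters indexed by the *opposite* vertex
    fb = np.empty((nt, 4, 3))
    for opp in range(4):
        others = [i for i in range(4) if i != opp]
        fb[:, opp] = x[:, others].mean(axis=1)
    for e, (a, b) in enumerate(TET_EDGE_PAIRS):
        others = [i for i in range(4) if i not in (a, b)]
        m = 0.5 * (x[:, a] + x[:, b])
        f1 = fb[:, others[0]]  # face (a, b, others[1])
        f2 = fb[:, others[1]]
        n = 0.5 * np.cross(f1 - m, c - m) + 0.5 * np.cross(c - m, f2 - m)
        # orient from a to b
        sign = np.sign(np.einsum("ij,ij->i", n, x[:, b] - x[:, a]))
        normals[:, e] = n * sign[:, None]
    return normals
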