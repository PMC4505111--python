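"""Programmatic generators for the simulation geometries.

All generators are deterministic and parametric (no randomized meshing):

* :func:`build_cylinder_domain` — a long intracellular cylinder (polygonal
  cross-section, prism extrusion) inside an extracellular shell; the
  verification geometry.
* :func:`build_sphere_domain` — an intracellular ball (icosphere surface)
  inside an extracellular shell; the multipole geometry.
* :func:`build_network_domain` — several idealized neurons (dendrite, soma,
  myelinated axon with nodes of Ranvier, synapse and stimulus patches) on a
  structured Kuhn-tetrahedral grid.
* :func:`build_parallel_cylinders` — a reduced two-or-more plain-cylinder
  arrangement used by the ephaptic-interaction experiment.

The mesh truncates the unbounded extracellular space at a finite margin;
the far boundary condition is owned by the solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Mesh, Patch, Subdomain, extract_membrane, tet_volumes

__all__ = [
    "build_cylinder_domain",
    "build_sphere_domain",
    "build_network_domain",
    "build_parallel_cylinders",
    "NeuronGeometrySpec",
    "icosphere",
]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _graded_steps(extent: float, first: float, growth: float = 1.8) -> np.ndarray:
    """Monotone step sizes covering ``extent``, starting near ``first`` and
    growing geometrically, rescaled to sum exactly to ``extent``."""
    steps = []
    s, total = float(first), 0.0
    while total < extent - 1e-12:
        steps.append(s)
        total += s
        s *= growth
    steps = np.array(steps)
    return steps * (extent / steps.sum())


def _finalize(vertices, tets, sub, cell, classify, markers=None) -> Mesh:
    """Orient tets positively, extract/classify the membrane, build the Mesh."""
    tets = np.asarray(tets, dtype=np.int64)
    vertices = np.asarray(vertices, dtype=float)
    vols = tet_volumes(vertices, tets)
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    sub = np.asarray(sub, dtype=np.int64)
    cell = np.asarray(cell, dtype=np.int64)
    mem_tris, tri_cell = extract_membrane(vertices, tets, sub, cell)
    centers = vertices[mem_tris].mean(axis=1) if len(mem_tris) else np.zeros((0, 3))
    tri_patch = np.array(
        [classify(int(c), p) for c, p in zip(tri_cell, centers)], dtype=np.int64
    )
    return Mesh(
        vertices=vertices,
        tets=tets,
        tet_subdomain=sub,
        tet_cell=cell,
        mem_tris=mem_tris,
        tri_patch=tri_patch,
        tri_cell=tri_cell,
        markers=markers or {},
    )


def _prism_tets(tri, bottom, top):
    """Split the prism over template triangle ``tri`` into 3 tets using the
    template-index diagonal rule (consistent across neighboring prisms)."""
    a, b, c = sorted(int(v) for v in tri)
    a0, b0, c0 = bottom[a], bottom[b], bottom[c]
    a1, b1, c1 = top[a], top[b], top[c]
    return ((a0, b0, c0, c1), (a0, b0, c1, b1), (a0, b1, c1, a1))


# ---------------------------------------------------------------------------
# cylinder
# ---------------------------------------------------------------------------


def build_cylinder_domain(
    length: float,
    diameter: float,
    extracellular_margin: float | None = None,
    resolution: float | None = None,
    *,
    n_theta: int = 8,
    axial_resolution: float | None = None,
    stimulus_length: float | None = None,
) -> Mesh:
    """Intracellular cylinder (regular ``n_theta``-gon cross-section, axis z,
    spanning ``0 <= z <= length``) embedded in an extracellular shell.

    Membrane patches default to ACTIVE with a STIMULUS patch at the z=0 end
    (end cap plus the first ``stimulus_length`` of lateral membrane).  Probe
    markers ``"end0"``, ``"mid"``, ``"end1"`` sit on the axis at the two ends
    and the midpoint.

    ``resolution`` controls the radial ring spacing and, unless
    ``axial_resolution`` is given, the slab thickness; it must not exceed the
    diameter (the cross-section could not be resolved).
    """
    if length <= 0 or diameter <= 0:
        raise ValueError("length and diameter must be positive")
    r = diameter / 2.0
    if resolution is None:
        resolution = r
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if resolution > diameter:
        raise ValueError("resolution larger than diameter: cannot resolve cross-section")
    if extracellular_margin is None:
        extracellular_margin = 5.0 * diameter
    if n_theta < 3:
        raise ValueError("n_theta must be >= 3")
    dz = axial_resolution or resolution
    if stimulus_length is None:
        stimulus_length = dz

    # radial template: center + intra rings up to r + graded extra rings
    n_in = max(1, int(round(r / resolution)))
    radii_in = [r * i / n_in for i in range(1, n_in + 1)]
    radii_out = (r + np.cumsum(_graded_steps(extracellular_margin, resolution))).tolist()
    radii = radii_in + radii_out
    membrane_ring = n_in  # 1-based ring index whose radius is exactly r

    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    pts2d = [np.zeros((1, 2))]
    for rr in radii:
        pts2d.append(np.column_stack([rr * np.cos(theta), rr * np.sin(theta)]))
    pts2d = np.vstack(pts2d)

    def ring_vertex(ring, k):  # ring 0 is the center point
        return 0 if ring == 0 else 1 + (ring - 1) * n_theta + (k % n_theta)

    tris2d, tri_ring = [], []  # template triangles + their max ring index
    for k in range(n_theta):
        tris2d.append((0, ring_vertex(1, k), ring_vertex(1, k + 1)))
        tri_ring.append(1)
    for ring in range(1, len(radii)):
        for k in range(n_theta):
            i0, i1 = ring_vertex(ring, k), ring_vertex(ring, k + 1)
            j0, j1 = ring_vertex(ring + 1, k), ring_vertex(ring + 1, k + 1)
            tris2d.append((i0, i1, j1))
            tris2d.append((i0, j1, j0))
            tri_ring.extend([ring + 1, ring + 1])
    tri_intra2d = np.array(tri_ring) <= membrane_ring

    # z planes: graded margin below 0, uniform core, graded margin above L
    nz = max(1, int(round(length / dz)))
    z_core = np.linspace(0.0, length, nz + 1)
    z_down = -np.cumsum(_graded_steps(extracellular_margin, dz))[::-1]
    z_up = length + np.cumsum(_graded_steps(extracellular_margin, dz))
    z_planes = np.concatenate([z_down, z_core, z_up])
    core_lo, core_hi = len(z_down), len(z_down) + nz  # slab index range of core

    n2d = len(pts2d)
    vertices = np.empty((len(z_planes) * n2d, 3))
    for i, z in enumerate(z_planes):
        vertices[i * n2d : (i + 1) * n2d, :2] = pts2d
        vertices[i * n2d : (i + 1) * n2d, 2] = z

    tets, sub, cell = [], [], []
    for slab in range(len(z_planes) - 1):
        bottom = np.arange(n2d) + slab * n2d
        top = bottom + n2d
        in_core = core_lo <= slab < core_hi
        for t, tri in enumerate(tris2d):
            intra = in_core and tri_intra2d[t]
            for tet in _prism_tets(tri, bottom, top):
                tets.append(tet)
                sub.append(Subdomain.INTRA if intra else Subdomain.EXTRA)
                cell.append(0 if intra else -1)

    def classify(cell_id, p):
        return Patch.STIMULUS if p[2] <= stimulus_length else Patch.ACTIVE

    axis = lambda z: int(core_lo * n2d + round(z / length * nz) * n2d)
    markers = {"end0": axis(0.0), "mid": axis(length / 2.0), "end1": axis(length)}
    return _finalize(vertices, tets, sub, cell, classify, markers)


# ---------------------------------------------------------------------------
# sphere
# ---------------------------------------------------------------------------


def icosphere(subdivisions: int):
    """Unit icosphere: returns (directions (nv,3), triangles (nf,3)) with
    ``20 * 4**subdivisions`` triangles."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = list(verts)
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}

        def mid(a, b):
            key = (a, b) if a < b else (b, a)
            idx = cache.get(key)
            if idx is None:
                v = verts[a] + verts[b]
                verts.append(v / np.linalg.norm(v))
                cache[key] = idx = len(verts) - 1
            return idx

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return np.array(verts), np.array(faces, dtype=np.int64)


def build_sphere_domain(
    radius: float,
    extracellular_radius: float,
    resolution: float | None = None,
    *,
    subdivisions: int | None = None,
    stimulus_direction=None,
    stimulus_angle_deg: float = 0.0,
    radial_growth: float = 1.8,
) -> Mesh:
    """Intracellular ball of ``radius`` inside an extracellular shell reaching
    ``extracellular_radius``; the membrane is a triangulated (ico)sphere.

    If ``stimulus_direction`` is given, membrane triangles within
    ``stimulus_angle_deg`` of that direction are labeled STIMULUS.
    """
    if not (extracellular_radius > radius > 0):
        raise ValueError("require extracellular_radius > radius > 0")
    if subdivisions is None:
        if resolution is None:
            resolution = radius / 2.0
        # icosahedron edge length is ~1.05 R; halves per subdivision
        subdivisions = max(0, int(np.ceil(np.log2(1.0514 * radius / resolution))))
    dirs, faces = icosphere(subdivisions)
    if resolution is None:
        resolution = radius / 2.0

    n_in = max(1, int(round(radius / resolution)))
    radii_in = [radius * i / n_in for i in range(1, n_in + 1)]
    margin = extracellular_radius - radius
    radii_out = (radius + np.cumsum(_graded_steps(margin, resolution, radial_growth))).tolist()
    radii = radii_in + radii_out
    n_shell_in = n_in

    nd = len(dirs)
    vertices = [np.zeros((1, 3))]
    for rr in radii:
        vertices.append(rr * dirs)
    vertices = np.vstack(vertices)

    def shell_vertex(shell, k):  # shell 0 = center point
        return 0 if shell == 0 else 1 + (shell - 1) * nd + k

    tets, sub, cell = [], [], []
    for a, b, c in faces:  # innermost: center-to-first-shell tets
        tets.append((0, shell_vertex(1, a), shell_vertex(1, b), shell_vertex(1, c)))
        intra = 1 <= n_shell_in
        sub.append(Subdomain.INTRA if intra else Subdomain.EXTRA)
        cell.append(0 if intra else -1)
    for shell in range(1, len(radii)):
        bottom = np.array([shell_vertex(shell, k) for k in range(nd)])
        top = np.array([shell_vertex(shell + 1, k) for k in range(nd)])
        intra = shell + 1 <= n_shell_in
        for tri in faces:
            for tet in _prism_tets(tri, bottom, top):
                tets.append(tet)
                sub.append(Subdomain.INTRA if intra else Subdomain.EXTRA)
                cell.append(0 if intra else -1)

    if stimulus_direction is not None:
        d = np.asarray(stimulus_direction, float)
        d = d / np.linalg.norm(d)
        cos_cap = np.cos(np.deg2rad(stimulus_angle_deg))

        def classify(cell_id, p):
            u = p / np.linalg.norm(p)
            return Patch.STIMULUS if float(u @ d) >= cos_cap else Patch.ACTIVE

    else:

        def classify(cell_id, p):
            return Patch.ACTIVE

    return _finalize(vertices, tets, sub, cell, classify, {"center": 0})


# ---------------------------------------------------------------------------
# idealized neuron network (voxel / Kuhn grid)
# ---------------------------------------------------------------------------


@dataclass
class NeuronGeometrySpec:
    """Parametric description of one idealized neuron, replicated per cell.

    Each cell lies along the x axis: a dendrite segment, a spherical soma and
    a myelinated axon with regularly spaced nodes of Ranvier.  Cells are
    stacked along y, separated by ``cell_spacing`` of extracellular space.
    All lengths in um.
    """

    soma_diameter: float = 20.0
    axon_diameter: float = 5.0
    axon_length: float = 60.0
    dendrite_diameter: float = 10.0
    dendrite_length: float = 30.0
    node_spacing: float = 16.0  #: myelinated internode length
    node_length: float = 4.0  #: active node-of-Ranvier length
    synapses: tuple = ()  #: (pre_cell, post_cell) pairs
    stimulus_cells: tuple = (0,)
    extracellular_margin: float = 20.0
    resolution: float = 2.5  #: voxel edge length
    cell_spacing: float = 25.0

    def validate(self, n_cells: int) -> None:
        for name in (
            "soma_diameter",
            "axon_diameter",
            "dendrite_diameter",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for pre, post in self.synapses:
            if pre == post:
                raise ValueError("synapse pre/post patches must lie on distinct cells")
            if not (0 <= pre < n_cells and 0 <= post < n_cells):
                raise ValueError("synapse references a cell outside the network")
        if self.cell_spacing <= 0:
            raise ValueError("cells must be non-overlapping (cell_spacing > 0)")


_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _voxel_mesh(origin, shape, h, inside_fns, classify, markers_at=None):
    """Kuhn-tetrahedral mesh of a box grid; tets labeled by which cell's
    ``inside`` predicate holds at their barycenter (overlaps rejected)."""
    nx, ny, nz = shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx + 1), np.arange(ny + 1), np.arange(nz + 1), indexing="ij"
    )
    vertices = origin + h * np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                base = np.array([i, j, k])
                for perm in _KUHN_PERMS:
                    path = [base.copy()]
                    for axis in perm:
                        nxt = path[-1].copy()
                        nxt[axis] += 1
                        path.append(nxt)
                    tets.append(tuple(vid(*p) for p in path))
    tets = np.asarray(tets, dtype=np.int64)

    bary = vertices[tets].mean(axis=1)
    cell = np.full(len(tets), -1, dtype=np.int64)
    for ci, fn in enumerate(inside_fns):
        mask = fn(bary)
        clash = mask & (cell >= 0)
        if clash.any():
            raise ValueError(f"overlapping cell volumes (cells {int(cell[clash][0])} and {ci})")
        cell[mask] = ci
    sub = np.where(cell >= 0, int(Subdomain.INTRA), int(Subdomain.EXTRA))

    # cells must not share vertices either, or their membrane potentials
    # would couple through the intracellular operator
    seen = {}
    for ci in range(len(inside_fns)):
        vs = np.unique(tets[cell == ci])
        for cj, other in seen.items():
            if np.intersect1d(vs, other, assume_unique=True).size:
                raise ValueError(
                    f"overlapping cell volumes (cells {cj} and {ci} share mesh "
                    "vertices; increase their separation)"
                )
        seen[ci] = vs

    mesh = _finalize(vertices, tets, sub, cell, classify, {})
    if markers_at:
        for name, spec in markers_at.items():
            point, cell_id = spec if isinstance(spec, tuple) and len(spec) == 2 else (spec, None)
            if cell_id is None:
                cand = np.arange(mesh.n_vertices)
            else:  # bind to a membrane vertex of the requested cell
                cand = np.unique(mesh.mem_tris[mesh.tri_cell == cell_id])
            d = np.linalg.norm(mesh.vertices[cand] - np.asarray(point, float), axis=1)
            mesh.markers[name] = int(cand[np.argmin(d)])
    return mesh


def build_network_domain(spec: NeuronGeometrySpec, n_cells: int) -> Mesh:
    """Multi-cell idealized-neuron mesh with per-cell patch labels.

    Per cell: passive DENDRITE, ACTIVE soma and nodes of Ranvier, MYELIN
    internodes, SYNAPSE_PRE at the presynaptic axon tip, SYNAPSE_POST on the
    postsynaptic cell's dendrite, STIMULUS on designated cells' distal
    dendrites.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    spec.validate(n_cells)
    h = spec.resolution
    Ld, Ds, La = spec.dendrite_length, spec.soma_diameter, spec.axon_length
    length = Ld + Ds + La
    width = max(spec.soma_diameter, spec.dendrite_diameter, spec.axon_diameter)
    pitch = width + spec.cell_spacing
    m = spec.extracellular_margin

    y_centers = [i * pitch for i in range(n_cells)]
    soma_c = Ld + Ds / 2.0

    def make_inside(yc):
        def inside(p):
            x, y, z = p[:, 0], p[:, 1], p[:, 2]
            rd = np.hypot(y - yc, z)
            dend = (x >= 0) & (x < Ld) & (rd < spec.dendrite_diameter / 2.0)
            soma = (x - soma_c) ** 2 + (y - yc) ** 2 + z**2 < (Ds / 2.0) ** 2
            axon = (x >= Ld + Ds) & (x <= length) & (rd < spec.axon_diameter / 2.0)
            return dend | soma | axon

        return inside

    pre_cells = {pre for pre, _ in spec.synapses}
    post_cells = {post for _, post in spec.synapses}
    period = spec.node_spacing + spec.node_length

    def classify(cell_id, p):
        x = p[0]
        if x >= length - spec.node_length:  # axon tip
            return Patch.SYNAPSE_PRE if cell_id in pre_cells else Patch.ACTIVE
        if x >= Ld + Ds - h:  # axon: alternate nodes and myelin
            s = x - (Ld + Ds)
            return Patch.ACTIVE if (s % period) < spec.node_length else Patch.MYELIN
        if x >= Ld - h:  # soma
            return Patch.ACTIVE
        if cell_id in spec.stimulus_cells and x < spec.node_length:
            return Patch.STIMULUS  # distal dendrite stimulus area
        if cell_id in post_cells and Ld / 3.0 <= x < Ld / 3.0 + 2 * h:
            return Patch.SYNAPSE_POST
        return Patch.DENDRITE

    origin = np.array([-m, y_centers[0] - width / 2.0 - m, -width / 2.0 - m])
    extent = np.array(
        [
            length + 2 * m,
            (y_centers[-1] - y_centers[0]) + width + 2 * m,
            width + 2 * m,
        ]
    )
    shape = tuple(int(np.ceil(e / h)) for e in extent)
    markers = {
        f"cell{i}_soma": ((soma_c, yc, spec.soma_diameter / 2.0), i)
        for i, yc in enumerate(y_centers)
    }
    return _voxel_mesh(
        origin, shape, h, [make_inside(yc) for yc in y_centers], classify, markers
    )


def build_parallel_cylinders(
    n_cells: int = 2,
    *,
    length: float = 32.0,
    diameter: float = 8.0,
    gap: float = 4.0,
    margin: float = 8.0,
    resolution: float = 2.0,
    stimulus_length: float = 6.0,
) -> Mesh:
    """Reduced geometry for the ephaptic experiment: ``n_cells`` plain active
    cylinders lying side by side along x, each with a STIMULUS patch at its
    x=0 end.  Probe markers ``"cellN_mid"`` sit on each membrane midpoint on
    the side facing the neighboring cell."""
    h = resolution
    r = diameter / 2.0
    y_centers = [i * (diameter + gap) for i in range(n_cells)]

    def make_inside(yc):
        def inside(p):
            x, y, z = p[:, 0], p[:, 1], p[:, 2]
            return (
                (x >= 0)
                & (x <= length)
                & (np.hypot(y - yc, z) < r)
            )

        return inside

    def classify(cell_id, p):
        return Patch.STIMULUS if p[0] <= stimulus_length else Patch.ACTIVE

    origin = np.array([-margin, y_centers[0] - r - margin, -r - margin])
    extent = np.array(
        [length + 2 * margin, (y_centers[-1] - y_centers[0]) + 2 * r + 2 * margin, 2 * r + 2 * margin]
    )
    shape = tuple(int(np.ceil(e / h)) for e in extent)
    markers = {}
    for i, yc in enumerate(y_centers):
        toward = -r if i == n_cells - 1 and n_cells > 1 else r
        markers[f"cell{i}_mid"] = ((length / 2.0, yc + toward, 0.0), i)
    return _voxel_mesh(
        origin, shape, h, [make_inside(yc) for yc in y_centers], classify, markers
    )
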