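"""Vertex-centered finite-volume solver for the 3D cable equation.

The coupled system solved per implicit-Euler time step is

* extracellular:  -div(sigma_out grad Phi_out) = 0 in Omega_out, with the
  membrane Neumann flux  -sigma_out grad Phi_out . n_in->out = j_all(V_m);
* extension:      -div(grad Phi_out^IN) = 0 in Omega_in with the Dirichlet
  coupling Phi_out^IN = Phi_out on the membrane (the harmonic continuation
  of the extracellular potential into the cell);
* membrane potential: -div(sigma_in grad V_m) = 0 in Omega_in with
  -sigma_in grad V_m . n_in->out = j_all(V_m) + j_eph, where the ephaptic
  current j_eph = sigma_in grad Phi_out^IN . n_in->out carries the
  extracellular field's feedback onto the membrane (togglable).

Control volumes are the barycentric boxes of the dual grid; stiffness
entries are the exact analytic integrals of the piecewise-linear shape
function gradients over the pre-integrated dual sub-faces.  The membrane
nonlinearity (Hodgkin-Huxley channels through the implicit gating update) is
resolved with Newton's method; the sparse linear systems are solved directly
(sparse LU) or with ILU-preconditioned BiCGstab.

The far (truncation) boundary of the extracellular space is grounded
(Phi_out = 0) by default; an insulated variant with a one-point gauge pin is
available because the pure-Neumann problem is singular.

Internal units: um, ms, mV; assembled conductances in uS, fluxes in nA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .membrane import GatingState, MembraneModel, advance_gating
from .mesh.core import Mesh, Patch, Subdomain
from .mesh.dual import TET_EDGE_PAIRS, DualGrid, build_dual_grid
from .units import UA_PER_CM2_TO_NA_PER_UM2, sigma_to_internal

__all__ = [
    "SolverConfig",
    "SystemState",
    "Assembly",
    "assemble_stiffness",
    "build_assembly",
    "residual",
    "ephaptic_flux",
    "newton_solve",
    "run_simulation",
    "total_membrane_flux",
    "solve_laplace",
    "SimulationResult",
]


# ---------------------------------------------------------------------------
# configuration and state containers
# ---------------------------------------------------------------------------


@dataclass
class SolverConfig:
    """Time stepping, Newton and linear-solver settings."""

    dt: float = 0.01  #: ms (10 us)
    t_end: float = 1.0  #: ms
    newton_abs_tol: float = 1e-6  #: nA, on the residual l1-norm
    newton_rel_tol: float = 1e-10
    newton_max_iter: int = 12
    gating_mode: str = "monolithic"  #: or "staggered"
    far_boundary: str = "grounded"  #: or "insulated"
    linear_solver: str = "ilu_bicgstab"  #: or "direct"
    linear_tol: float = 1e-10
    linear_max_iter: int = 500
    record_every: int = 1

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.newton_abs_tol <= 0 or self.newton_rel_tol <= 0:
            raise ValueError("Newton tolerances must be positive")
        if self.gating_mode not in ("monolithic", "staggered"):
            raise ValueError("gating_mode must be 'monolithic' or 'staggered'")
        if self.far_boundary not in ("grounded", "insulated"):
            raise ValueError("far_boundary must be 'grounded' or 'insulated'")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))


@dataclass
class SystemState:
    """Nodal coefficients of the three fields plus gating, at one time level.

    ``phi_out`` lives on the extracellular vertex set, ``phi_out_in`` (the
    extension field) and ``v_m`` on the intracellular vertex set, gating on
    the membrane vertices.  After a converged step the Dirichlet coupling
    phi_out_in = phi_out holds on the membrane to solver tolerance.
    """

    phi_out: np.ndarray
    phi_out_in: np.ndarray
    v_m: np.ndarray
    gating: GatingState
    t: float = 0.0

    def copy(self) -> "SystemState":
        return SystemState(
            self.phi_out.copy(),
            self.phi_out_in.copy(),
            self.v_m.copy(),
            self.gating.copy(),
            self.t,
        )


# ---------------------------------------------------------------------------
# stiffness assembly
# ---------------------------------------------------------------------------


def _shape_gradients(verts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Constant P1 shape-function gradients per tet, shape (nt, 4, 3)."""
    x = verts[tets]
    d = np.stack([x[:, i] - x[:, 0] for i in (1, 2, 3)], axis=2)  # columns
    dinv = np.linalg.inv(d)
    grads = np.empty((len(tets), 4, 3))
    grads[:, 1:, :] = dinv
    grads[:, 0, :] = -dinv.sum(axis=1)
    return grads


def assemble_stiffness(
    mesh: Mesh, dual: DualGrid, sigma: float, subdomain: Subdomain
):
    """Finite-volume stiffness of one subdomain.

    Entry ``a_kj = \\oint_{dB_k} sigma grad b_j . n dS`` over the interior
    dual sub-faces of the subdomain (exact, since the P1 gradients are
    constant per tet and the sub-face normals are pre-integrated).  Rows over
    interior vertices sum to zero.

    ``sigma`` is in mS/cm.  Returns ``(S, vertex_ids)`` with ``S`` a CSR
    matrix over the subdomain's local vertex numbering and ``vertex_ids`` the
    corresponding global indices.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    mask = mesh.tet_subdomain == subdomain
    if not mask.any():
        raise ValueError(f"subdomain {subdomain!r} contains no tetrahedra")
    tets = mesh.tets[mask]
    normals = dual.subface_normals[mask]  # (nt, 6, 3) oriented low->high local
    grads = _shape_gradients(mesh.vertices, tets)
    sig = sigma_to_internal(sigma)

    # outward integrated normal of each vertex's sub-volume within the tet
    n_k = np.zeros((len(tets), 4, 3))
    for e, (a, b) in enumerate(TET_EDGE_PAIRS):
        n_k[:, a] += normals[:, e]
        n_k[:, b] -= normals[:, e]

    # a_local[k, m] = sigma * grad_m . N_k
    a_local = sig * np.einsum("tkc,tmc->tkm", n_k, grads)

    vertex_ids = np.unique(tets)
    g2l = np.full(mesh.n_vertices, -1, dtype=np.int64)
    g2l[vertex_ids] = np.arange(len(vertex_ids))
    loc = g2l[tets]  # (nt, 4)
    rows = np.repeat(loc, 4, axis=1).ravel()
    cols = np.tile(loc, (1, 4)).ravel()
    S = sp.coo_matrix(
        (a_local.ravel(), (rows, cols)), shape=(len(vertex_ids), len(vertex_ids))
    ).tocsr()
    return S, vertex_ids


# ---------------------------------------------------------------------------
# coupled-system assembly context
# ---------------------------------------------------------------------------


@dataclass
class Assembly:
    """Precomputed operators and index maps of the coupled system."""

    mesh: Mesh
    dual: DualGrid
    sigma_in: float  #: mS/cm
    sigma_out: float  #: mS/cm
    S_in: sp.csr_matrix
    S_out: sp.csr_matrix
    intra_ids: np.ndarray  #: global vertex ids of the intracellular numbering
    extra_ids: np.ndarray
    mem_ids: np.ndarray  #: global ids of membrane vertices (ordered)
    mem_in: np.ndarray  #: membrane positions in the intra numbering
    mem_out: np.ndarray  #: membrane positions in the extra numbering
    mem_cell: np.ndarray  #: owning cell per membrane vertex
    outer_extra: np.ndarray  #: far-boundary rows in the extra numbering
    patch_groups: list = field(default_factory=list)
    #: (patch, cell, mem-index array, per-vertex areas um^2, total area um^2)

    @property
    def n_cells(self) -> int:
        return self.mesh.n_cells


def build_assembly(mesh: Mesh, sigma_in: float, sigma_out: float, dual=None) -> Assembly:
    """Assemble both stiffness operators and all membrane bookkeeping."""
    if dual is None:
        dual = build_dual_grid(mesh)
    S_in, intra_ids = assemble_stiffness(mesh, dual, sigma_in, Subdomain.INTRA)
    S_out, extra_ids = assemble_stiffness(mesh, dual, sigma_out, Subdomain.EXTRA)

    mem_ids = mesh.membrane_vertices()
    g2l_in = np.full(mesh.n_vertices, -1, dtype=np.int64)
    g2l_in[intra_ids] = np.arange(len(intra_ids))
    g2l_out = np.full(mesh.n_vertices, -1, dtype=np.int64)
    g2l_out[extra_ids] = np.arange(len(extra_ids))
    mem_in = g2l_in[mem_ids]
    mem_out = g2l_out[mem_ids]
    if (mem_in < 0).any() or (mem_out < 0).any():
        raise ValueError("membrane vertices must belong to both subdomains")
    mem_cell = dual.cell_of_vertex[mem_ids]

    # far boundary: faces owned by exactly one tet, restricted to EXTRA side
    from .mesh.core import _tet_face_map

    face_map = _tet_face_map(mesh.tets)
    outer = set()
    for key, owners in face_map.items():
        if len(owners) == 1 and mesh.tet_subdomain[owners[0]] == Subdomain.EXTRA:
            outer.update(key)
    outer_extra = np.array(sorted(g2l_out[list(outer)]), dtype=np.int64)

    g2m = np.full(mesh.n_vertices, -1, dtype=np.int64)
    g2m[mem_ids] = np.arange(len(mem_ids))
    patch_groups = []
    for patch in Patch:
        areas_global = dual.membrane_area[patch]
        for cell in range(max(mesh.n_cells, 1)):
            sel = mesh.tri_cell == cell
            verts = np.unique(mesh.mem_tris[(mesh.tri_patch == patch) & sel])
            if len(verts) == 0:
                continue
            areas = areas_global[verts]
            keep = areas > 0
            verts, areas = verts[keep], areas[keep]
            if len(verts) == 0:
                continue
            patch_groups.append(
                (Patch(patch), cell, g2m[verts], areas, float(areas.sum()))
            )

    return Assembly(
        mesh=mesh,
        dual=dual,
        sigma_in=sigma_in,
        sigma_out=sigma_out,
        S_in=S_in,
        S_out=S_out,
        intra_ids=intra_ids,
        extra_ids=extra_ids,
        mem_ids=mem_ids,
        mem_in=mem_in,
        mem_out=mem_out,
        mem_cell=mem_cell,
        outer_extra=outer_extra,
        patch_groups=patch_groups,
    )


def rest_state(asm: Assembly, v_rest: float = 0.0) -> SystemState:
    return SystemState(
        phi_out=np.zeros(len(asm.extra_ids)),
        phi_out_in=np.zeros(len(asm.intra_ids)),
        v_m=np.full(len(asm.intra_ids), v_rest),
        gating=GatingState.rest(len(asm.mem_ids), v_rest),
        t=0.0,
    )


# ---------------------------------------------------------------------------
# membrane flux and residual
# ---------------------------------------------------------------------------


def _membrane_flux(
    asm: Assembly,
    model: MembraneModel,
    v_mem: np.ndarray,
    v_mem_prev: np.ndarray,
    gating: GatingState,
    t: float,
    dt: float,
    syn_densities: dict,
) -> np.ndarray:
    """Integrated transmembrane current F_k (nA) per membrane vertex:
    sum over patches of area * j_all."""
    dvdt = (v_mem - v_mem_prev) / dt
    F = np.zeros(len(asm.mem_ids))
    for patch, cell, idx, areas, total in asm.patch_groups:
        j = model.total_current_density(
            patch,
            v_mem[idx],
            dvdt[idx],
            (gating.n[idx], gating.m[idx], gating.h[idx]),
            t,
            cell=cell,
            patch_area_um2=total,
            synapse_densities=syn_densities,
        )
        F[idx] += areas * UA_PER_CM2_TO_NA_PER_UM2 * j
    return F


def _gating_for(asm, config, prev: SystemState, v_mem, dt):
    if config.gating_mode == "monolithic":
        return advance_gating(prev.gating, v_mem, dt)
    return advance_gating(prev.gating, prev.v_m[asm.mem_in], dt)


def _synapse_densities(asm: Assembly, model: MembraneModel, prev: SystemState, t: float) -> dict:
    """Update synapse latches from the previous step's presynaptic potential
    and return post-patch current densities keyed by post cell id."""
    densities: dict = {}
    if not model.synapses:
        return densities
    pre_groups = {
        cell: (idx, areas, total)
        for patch, cell, idx, areas, total in asm.patch_groups
        if patch == Patch.SYNAPSE_PRE
    }
    post_groups = {
        cell: total
        for patch, cell, idx, areas, total in asm.patch_groups
        if patch == Patch.SYNAPSE_POST
    }
    v_mem_prev = prev.v_m[asm.mem_in]
    for syn in model.synapses:
        idx, areas, total = pre_groups[syn.pre_cell]
        v_pre = float((v_mem_prev[idx] * areas).sum() / total)
        syn.update_latch(v_pre, t)
        post_area = post_groups.get(syn.post_cell)
        if post_area is None:
            continue
        densities[syn.post_cell] = densities.get(syn.post_cell, 0.0) + syn.current_density(
            t, post_area
        )
    return densities


def residual(
    asm: Assembly,
    model: MembraneModel,
    state: SystemState,
    prev: SystemState,
    dt: float,
    *,
    ephaptic: bool = True,
    config: SolverConfig | None = None,
    syn_densities: dict | None = None,
    gating: GatingState | None = None,
):
    """Concatenated finite-volume residual [R_out, R_ext, R_vm] (nA).

    ``R_out``: extracellular Laplace rows plus the membrane source +F_k,
    far-boundary rows replaced by the Dirichlet/gauge condition.
    ``R_ext``: extension Laplace rows; membrane rows replaced by the
    Dirichlet coupling phi_out_in - phi_out.
    ``R_vm``: membrane-potential Laplace rows with the sink -F_k and, when
    the ephaptic current is enabled, +(S_in phi_out_in)_k (= -j_eph area
    flux) on membrane rows.
    """
    config = config or SolverConfig()
    if syn_densities is None:
        syn_densities = _synapse_densities(asm, model, prev, state.t)
    v_mem = state.v_m[asm.mem_in]
    if gating is None:
        gating = _gating_for(asm, config, prev, v_mem, dt)
    F = _membrane_flux(
        asm, model, v_mem, prev.v_m[asm.mem_in], gating, state.t, dt, syn_densities
    )

    R_out = asm.S_out @ state.phi_out
    np.add.at(R_out, asm.mem_out, F)
    if config.far_boundary == "grounded":
        R_out[asm.outer_extra] = state.phi_out[asm.outer_extra]
    else:  # insulated: natural zero-Neumann, one-point gauge pin
        pin = asm.outer_extra[:1]
        R_out[pin] = state.phi_out[pin]

    s_ext = asm.S_in @ state.phi_out_in
    R_ext = s_ext.copy()
    R_ext[asm.mem_in] = state.phi_out_in[asm.mem_in] - state.phi_out[asm.mem_out]

    R_vm = asm.S_in @ state.v_m
    R_vm[asm.mem_in] -= F
    if ephaptic:
        R_vm[asm.mem_in] += s_ext[asm.mem_in]
    return np.concatenate([R_out, R_ext, R_vm]), F, gating


def ephaptic_flux(asm: Assembly, state: SystemState) -> np.ndarray:
    """Per-membrane-vertex ephaptic current (nA): the finite-volume boundary
    flux of the extension field through the membrane piece of each control
    volume, scaled by sigma_in.  Recovered as the consistent flux
    -(S_in phi_out_in)_k at membrane rows."""
    return -(asm.S_in @ state.phi_out_in)[asm.mem_in]


def membrane_flux_density(asm: Assembly, F: np.ndarray) -> np.ndarray:
    """Convert integrated per-vertex membrane currents F (nA) to current
    densities j_all (uA/cm^2) using the dual-grid membrane areas."""
    areas = asm.dual.membrane_area_total[asm.mem_ids]
    return F / (areas * UA_PER_CM2_TO_NA_PER_UM2)


def total_membrane_flux(asm: Assembly, F: np.ndarray, cell: int | None = None) -> float:
    """Area-weighted total transmembrane current (nA), per cell or overall;
    vanishes at every converged step (the discrete no-monopole identity)."""
    if cell is None:
        return float(F.sum())
    return float(F[asm.mem_cell == cell].sum())


# ---------------------------------------------------------------------------
# Newton solver
# ---------------------------------------------------------------------------


def _flux_derivative(
    asm, model, v_mem, v_mem_prev, prev_gating, t, dt, syn_densities, config
):
    """Diagonal dF/dV at membrane vertices by one-sided finite differences of
    the composed map V -> (implicit gating) -> j_all (the capacitive c_m/dt
    term is part of j_all and dominates the diagonal)."""
    eps = 1e-4

    def flux_at(v):
        if config.gating_mode == "monolithic":
            g = advance_gating(prev_gating, v, dt)
        else:
            g = advance_gating(prev_gating, v_mem_prev, dt)
        return _membrane_flux(asm, model, v, v_mem_prev, g, t, dt, syn_densities)

    return (flux_at(v_mem + eps) - flux_at(v_mem)) / eps


def _jacobian_constant(asm, config, ephaptic):
    """Everything in the Jacobian except the dF/dV membrane diagonals."""
    n_out, n_in = asm.S_out.shape[0], asm.S_in.shape[0]
    mem_n = len(asm.mem_ids)

    # extracellular block with far-boundary rows replaced
    S_out = asm.S_out.tolil(copy=True)
    bnd = (
        asm.outer_extra if config.far_boundary == "grounded" else asm.outer_extra[:1]
    )
    S_out[bnd, :] = 0.0
    S_out[bnd, bnd] = 1.0
    J_oo = S_out.tocsr()

    # extension block: interior Laplace rows, Dirichlet coupling on membrane
    keep_in = np.ones(n_in)
    keep_in[asm.mem_in] = 0.0
    J_ee = (sp.diags(keep_in) @ asm.S_in + sp.coo_matrix(
        (np.ones(mem_n), (asm.mem_in, asm.mem_in)), shape=(n_in, n_in)
    )).tocsr()
    J_eo = sp.coo_matrix(
        (-np.ones(mem_n), (asm.mem_in, asm.mem_out)), shape=(n_in, n_out)
    ).tocsr()

    # membrane-potential block: Laplace part plus (if ephaptic) the membrane
    # rows of S_in acting on the extension field
    if ephaptic:
        J_ve = (sp.diags(1.0 - keep_in) @ asm.S_in).tocsr()
    else:
        J_ve = sp.csr_matrix((n_in, n_in))

    J0 = sp.bmat(
        [
            [J_oo, None, None],
            [J_eo, J_ee, None],
            [None, J_ve, asm.S_in],
        ],
        format="csr",
    )
    keep_out = np.ones(n_out)
    keep_out[bnd] = 0.0
    return J0, keep_out


def _jacobian(asm, dfdv, config, ephaptic):
    """Constant part + the dF/dV coupling diagonals (cached per assembly)."""
    key = (config.far_boundary, ephaptic)
    cache = getattr(asm, "_jac_cache", None)
    if cache is None:
        cache = asm._jac_cache = {}
    if key not in cache:
        cache[key] = _jacobian_constant(asm, config, ephaptic)
    J0, keep_out = cache[key]
    n_out, n_in = asm.S_out.shape[0], asm.S_in.shape[0]
    rows = np.concatenate([asm.mem_out, n_out + n_in + asm.mem_in])
    cols = np.concatenate([n_out + n_in + asm.mem_in, n_out + n_in + asm.mem_in])
    vals = np.concatenate([keep_out[asm.mem_out] * dfdv, -dfdv])
    D = sp.coo_matrix((vals, (rows, cols)), shape=J0.shape).tocsr()
    return (J0 + D).tocsc()


def _linear_solve(J, rhs, config, asm=None):
    """Solve J x = rhs.  The default ILU-preconditioned BiCGstab caches the
    incomplete factorization on the assembly and reuses it across Newton
    iterations and time steps (only the membrane diagonal of J changes, and
    its c_m/dt part not at all); the preconditioner is refreshed on failure
    with a sparse-LU fallback."""
    if config.linear_solver == "direct" or asm is None:
        return spla.splu(J).solve(rhs)

    cache = getattr(asm, "_ilu_cache", None)
    if cache is None:
        cache = asm._ilu_cache = {}

    def make_ilu():
        try:
            fac = spla.spilu(J, drop_tol=1e-5, fill_factor=20)
        except RuntimeError:  # zero pivot in the incomplete factorization
            fac = spla.splu(J)
        cache["M"] = spla.LinearOperator(J.shape, fac.solve)
        return cache["M"]

    M = cache.get("M") or make_ilu()
    for attempt in range(2):
        x, info = spla.bicgstab(
            J, rhs, rtol=config.linear_tol, atol=0.0,
            maxiter=config.linear_max_iter, M=M,
        )
        if info == 0:
            return x
        M = make_ilu()
    return spla.splu(J).solve(rhs)


class NewtonDivergence(RuntimeError):
    pass


def newton_solve(
    asm: Assembly,
    model: MembraneModel,
    prev: SystemState,
    dt: float,
    config: SolverConfig,
    *,
    ephaptic: bool = True,
):
    """Advance one implicit-Euler step with Newton iteration.

    Returns ``(state, info)`` where ``info`` has the iteration count, the
    final membrane flux vector F (nA) and the residual norm.  Raises
    :class:`NewtonDivergence` with diagnostics if ``newton_max_iter`` is
    exceeded (a smaller dt usually helps).
    """
    t_new = prev.t + dt
    state = prev.copy()
    state.t = t_new
    syn_densities = _synapse_densities(asm, model, prev, t_new)

    n_out, n_in = asm.S_out.shape[0], asm.S_in.shape[0]
    r0_norm = None
    for it in range(1, config.newton_max_iter + 1):
        R, F, gating = residual(
            asm,
            model,
            state,
            prev,
            dt,
            ephaptic=ephaptic,
            config=config,
            syn_densities=syn_densities,
        )
        # l1 norm: convergence then bounds |sum of flux rows|, i.e. the
        # discrete per-cell flux balance, by the same tolerance
        norm = np.abs(R).sum()
        if r0_norm is None:
            r0_norm = norm
        if norm <= max(config.newton_abs_tol, config.newton_rel_tol * r0_norm):
            state.gating = gating
            return state, {"iterations": it - 1, "flux": F, "residual_norm": norm}
        dfdv = _flux_derivative(
            asm,
            model,
            state.v_m[asm.mem_in],
            prev.v_m[asm.mem_in],
            prev.gating,
            t_new,
            dt,
            syn_densities,
            config,
        )
        J = _jacobian(asm, dfdv, config, ephaptic)
        delta = _linear_solve(J, -R, config, asm)
        state.phi_out += delta[:n_out]
        state.phi_out_in += delta[n_out : n_out + n_in]
        state.v_m += delta[n_out + n_in :]
    raise NewtonDivergence(
        f"Newton did not converge in {config.newton_max_iter} iterations at "
        f"t={t_new:.4f} ms (residual {norm:.3e} nA, initial {r0_norm:.3e}); "
        "consider a smaller dt"
    )


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    times: np.ndarray
    vm: dict  #: probe name -> V_m trace (mV)
    phi: dict  #: probe name -> Phi_out trace (mV)
    flux_balance: np.ndarray  #: (n_recorded, n_cells) total flux per cell (nA)
    newton_iterations: np.ndarray
    coupling_error: np.ndarray  #: max |phi_out_in - phi_out| on the membrane
    final_state: SystemState | None
    step_count: int
    assembly: Assembly | None = None


def run_simulation(
    mesh: Mesh,
    model: MembraneModel,
    config: SolverConfig,
    *,
    sigma_in: float = 2.0,
    sigma_out: float = 20.0,
    probes: dict | None = None,
    ephaptic: bool = True,
    dry_run: bool = False,
    state_callback=None,
) -> SimulationResult:
    """Advance the coupled system from rest over ``round(t_end/dt)`` steps.

    ``probes`` maps names to points or vertex ids; V_m is recorded at the
    nearest intracellular vertex and Phi_out at the nearest extracellular
    vertex of each probe.  With ``dry_run`` only the step count is computed
    (nothing is assembled).  ``state_callback(step, state, info)`` runs after
    every converged step.
    """
    steps = config.n_steps
    if dry_run:
        return SimulationResult(
            times=np.array([]), vm={}, phi={}, flux_balance=np.zeros((0, 0)),
            newton_iterations=np.array([], dtype=int), coupling_error=np.array([]),
            final_state=None, step_count=steps,
        )

    asm = build_assembly(mesh, sigma_in, sigma_out)
    state = rest_state(asm)
    probes = probes or {name: vid for name, vid in mesh.markers.items()}

    g2l_in = np.full(mesh.n_vertices, -1, dtype=np.int64)
    g2l_in[asm.intra_ids] = np.arange(len(asm.intra_ids))
    g2l_out = np.full(mesh.n_vertices, -1, dtype=np.int64)
    g2l_out[asm.extra_ids] = np.arange(len(asm.extra_ids))

    def resolve(p):
        if isinstance(p, (int, np.integer)):
            # explicit vertex: use it directly where it carries the field
            point = mesh.vertices[int(p)]
            i_in, i_out = int(g2l_in[int(p)]), int(g2l_out[int(p)])
        else:
            point = np.asarray(p, float)
            i_in = i_out = -1
        if i_in < 0:
            i_in = int(np.argmin(np.linalg.norm(mesh.vertices[asm.intra_ids] - point, axis=1)))
        if i_out < 0:
            i_out = int(np.argmin(np.linalg.norm(mesh.vertices[asm.extra_ids] - point, axis=1)))
        return i_in, i_out

    probe_idx = {name: resolve(p) for name, p in probes.items()}

    n_rec = steps // config.record_every + 1
    n_cells = max(asm.n_cells, 1)
    times = np.zeros(n_rec)
    vm = {name: np.zeros(n_rec) for name in probe_idx}
    phi = {name: np.zeros(n_rec) for name in probe_idx}
    flux = np.zeros((n_rec, n_cells))
    iters = np.zeros(n_rec, dtype=int)
    coup = np.zeros(n_rec)

    def record(row, info):
        times[row] = state.t
        for name, (i_in, i_out) in probe_idx.items():
            vm[name][row] = state.v_m[i_in]
            phi[name][row] = state.phi_out[i_out]
        if info is not None:
            for c in range(n_cells):
                flux[row, c] = total_membrane_flux(asm, info["flux"], c)
            iters[row] = info["iterations"]
        coup[row] = np.abs(
            state.phi_out_in[asm.mem_in] - state.phi_out[asm.mem_out]
        ).max()

    record(0, None)
    row = 0
    for step in range(1, steps + 1):
        state, info = newton_solve(asm, model, state, config.dt, config, ephaptic=ephaptic)
        if step % config.record_every == 0:
            row += 1
            record(row, info)
        if state_callback is not None:
            state_callback(step, state, info)

    return SimulationResult(
        times=times, vm=vm, phi=phi, flux_balance=flux, newton_iterations=iters,
        coupling_error=coup, final_state=state, step_count=steps, assembly=asm,
    )


# ---------------------------------------------------------------------------
# linear Laplace helper (patch tests, analytic oracles)
# ---------------------------------------------------------------------------


def solve_laplace(
    mesh: Mesh,
    subdomain: Subdomain,
    sigma: float,
    dirichlet_ids,
    dirichlet_values,
):
    """Solve -div(sigma grad u) = 0 on one subdomain with Dirichlet data on
    the given global vertex ids; returns u on the subdomain's vertex set as
    ``(u, vertex_ids)``."""
    dual = build_dual_grid(mesh)
    S, ids = assemble_stiffness(mesh, dual, sigma, subdomain)
    g2l = np.full(mesh.n_vertices, -1, dtype=np.int64)
    g2l[ids] = np.arange(len(ids))
    d_loc = g2l[np.asarray(dirichlet_ids, dtype=np.int64)]
    if (d_loc < 0).any():
        raise ValueError("Dirichlet vertex outside the subdomain")
    A = S.tolil(copy=True)
    A[d_loc, :] = 0.0
    A[d_loc, d_loc] = 1.0
    rhs = np.zeros(len(ids))
    rhs[d_loc] = np.asarray(dirichlet_values, dtype=float)
    u = spla.spsolve(A.tocsr().tocsc(), rhs)
    return u, ids
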