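"""Coupled finite-volume solver: assembly exactness, conservation, Newton."""

import numpy as np
import pytest

from neurocable3d import (
    HHParameters,
    MembraneModel,
    SolverConfig,
    StimulusSpec,
    Subdomain,
    assemble_stiffness,
    build_assembly,
    build_cylinder_domain,
    build_sphere_domain,
    e_l_for_rest,
    ephaptic_flux,
    membrane_flux_density,
    newton_solve,
    refine_uniform,
    residual,
    run_simulation,
    solve_laplace,
    total_membrane_flux,
)
from neurocable3d.fvm_core import rest_state
from neurocable3d.mesh.builders import _voxel_mesh
from neurocable3d.mesh.dual import build_dual_grid


def _box_mesh(n=3, h=1.0):
    """All-extracellular box of Kuhn tets (no cells): a pure Laplace domain."""
    return _voxel_mesh(
        np.zeros(3), (n, n, n), h, [], lambda c, p: 0, None
    )


class TestStiffness:
    def test_interior_row_sums_vanish(self, small_cylinder, cylinder_assembly):
        """Constants are in the kernel: every stiffness row sums to zero
        (membrane rows included; only flux terms break the balance)."""
        for S in (cylinder_assembly.S_in, cylinder_assembly.S_out):
            rowsum = np.asarray(abs(S @ np.ones(S.shape[1])))
            scale = abs(S.data).max()
            assert rowsum.max() < 1e-12 * scale

    def test_linear_patch_test_exact(self):
        """A linear potential imposed on the boundary of a Kuhn box is
        reproduced exactly at every interior node (P1 exactness)."""
        mesh = _box_mesh(3)
        bnd = []
        for v, p in enumerate(mesh.vertices):
            if np.any(p == 0.0) or np.any(p == 3.0):
                bnd.append(v)
        bnd = np.array(bnd)
        field = lambda p: 2.0 * p[:, 0] - 0.7 * p[:, 1] + 0.3 * p[:, 2] + 1.0
        u, ids = solve_laplace(mesh, Subdomain.EXTRA, 20.0, bnd, field(mesh.vertices[bnd]))
        assert np.abs(u - field(mesh.vertices[ids])).max() < 1e-10

    def test_harmonic_sphere_oracle_second_order(self):
        """Dirichlet data from the exterior harmonic z/r^3 on both boundaries
        of a spherical shell: the volume-weighted L2 error decreases at
        ~O(h^2) as the (curved) geometry and grid are refined together."""
        from neurocable3d.mesh.core import _tet_face_map

        exact = lambda p: p[:, 2] / np.linalg.norm(p, axis=1) ** 3
        errs = []
        for s, res in ((1, 0.5), (2, 0.25), (3, 0.125)):
            mesh = build_sphere_domain(
                1.0, 2.2, resolution=res, subdivisions=s, radial_growth=1.0
            )
            # structural boundary: membrane vertices + outer single-owner faces
            outer = set()
            for key, owners in _tet_face_map(mesh.tets).items():
                if len(owners) == 1 and mesh.tet_subdomain[owners[0]] == Subdomain.EXTRA:
                    outer.update(key)
            bnd = np.unique(np.concatenate([mesh.membrane_vertices(), np.array(sorted(outer))]))
            u, ids = solve_laplace(mesh, Subdomain.EXTRA, 20.0, bnd, exact(mesh.vertices[bnd]))
            w = build_dual_grid(mesh).volumes[Subdomain.EXTRA][ids]
            e = u - exact(mesh.vertices[ids])
            errs.append(np.sqrt((w * e**2).sum() / w.sum()))
        # halving h: ratio -> 4 for 2nd order (pre-asymptotic at the first pair)
        assert errs[0] / errs[1] > 2.0
        assert errs[1] / errs[2] > 3.0

    def test_empty_subdomain_rejected(self):
        mesh = _box_mesh(2)
        dual = build_dual_grid(mesh)
        with pytest.raises(ValueError, match="no tetrahedra"):
            assemble_stiffness(mesh, dual, 2.0, Subdomain.INTRA)


class TestResidual:
    def test_rest_is_stationary_without_conductances(self, cylinder_assembly):
        model = MembraneModel(params=HHParameters(g_na=0.0, g_k=0.0, g_l=0.0))
        st = rest_state(cylinder_assembly)
        R, F, _ = residual(cylinder_assembly, model, st, st, 0.01)
        assert np.abs(R).max() == 0.0 and np.abs(F).max() == 0.0

    def test_rest_is_stationary_with_balanced_leak(self, cylinder_assembly, balanced_model):
        st = rest_state(cylinder_assembly)
        R, _, _ = residual(cylinder_assembly, model := balanced_model, st, st, 0.01)
        assert np.abs(R).max() < 1e-12

    def test_extracellular_rows_match_dense_oracle(self, cylinder_assembly, balanced_model):
        """Residual equals the hand-composed S.phi + area-weighted flux."""
        asm = cylinder_assembly
        rng = np.random.default_rng(7)
        st = rest_state(asm)
        st.phi_out = rng.normal(size=len(asm.extra_ids))
        R, F, _ = residual(asm, balanced_model, st, st, 0.01, config=SolverConfig(far_boundary="insulated"))
        n_out = len(asm.extra_ids)
        expected = np.asarray(asm.S_out @ st.phi_out)
        expected[asm.mem_out] += F
        pin = asm.outer_extra[:1]
        expected[pin] = st.phi_out[pin]
        assert np.allclose(R[:n_out], expected, atol=1e-12)


class TestEphapticFlux:
    def test_constant_extension_gives_zero_flux(self, cylinder_assembly):
        st = rest_state(cylinder_assembly)
        st.phi_out_in[:] = 3.7
        J = ephaptic_flux(cylinder_assembly, st)
        scale = abs(cylinder_assembly.S_in.data).max()
        assert np.abs(J).max() < 1e-12 * scale

    def test_linear_extension_matches_analytic_normal_flux(self, cylinder_assembly):
        """phi^IN = z on the cylinder: the consistent boundary flux is
        sigma_in * n_z-component of each vertex's integrated membrane
        normal, exactly."""
        asm = cylinder_assembly
        st = rest_state(asm)
        z = asm.mesh.vertices[asm.intra_ids, 2]
        st.phi_out_in = z.copy()
        J = ephaptic_flux(asm, st)
        sig = 2.0 * 0.1  # mS/cm -> uS/um
        expected = sig * asm.dual.membrane_normal[asm.mem_ids, 2]
        assert np.allclose(J, expected, atol=1e-10 * np.abs(expected).max())


class TestNewton:
    def test_passive_linear_membrane_converges_in_one_iteration(self, cylinder_assembly):
        model = MembraneModel(
            params=HHParameters(g_na=0.0, g_k=0.0, e_l=0.0),
            stimuli=[StimulusSpec(cell=0, amplitude=10.0, t_on=0.0, t_off=1.0)],
        )
        cfg = SolverConfig(gating_mode="staggered")
        _, info = newton_solve(cylinder_assembly, model, rest_state(cylinder_assembly), 0.01, cfg)
        assert info["iterations"] == 1

    def test_active_step_converges_within_budget(self, cylinder_assembly, stimulated_model):
        cfg = SolverConfig()
        st = rest_state(cylinder_assembly)
        for _ in range(25):  # through stimulus onset and upstroke
            st, info = newton_solve(cylinder_assembly, stimulated_model, st, 0.01, cfg)
            assert info["iterations"] <= cfg.newton_max_iter
        assert st.v_m.max() > 1.0

    def test_backward_euler_first_order_in_dt(self, small_cylinder, balanced_model):
        """Richardson check: halving dt roughly halves the V_m error at a
        probe against a finer-dt reference (backward Euler is first order)."""
        model = MembraneModel(
            params=balanced_model.params,
            stimuli=[StimulusSpec(cell=0, amplitude=15.0, t_on=0.0, t_off=0.6)],
        )
        T = 0.4
        probes = {"p": small_cylinder.markers["end0"]}

        def v_at(dt):
            res = run_simulation(
                small_cylinder, model, SolverConfig(dt=dt, t_end=T), probes=probes
            )
            return res.vm["p"][-1]

        v1, v2, v4, v8 = v_at(0.04), v_at(0.02), v_at(0.01), v_at(0.005)
        e1, e2, e4 = abs(v1 - v8), abs(v2 - v8), abs(v4 - v8)
        assert e2 < e1 and e4 < e2
        assert e1 / e2 == pytest.approx(2.0, rel=0.5)

    def test_dirichlet_coupling_and_flux_balance(self, small_cylinder, stimulated_model):
        cfg = SolverConfig(dt=0.01, t_end=0.3)
        res = run_simulation(small_cylinder, stimulated_model, cfg)
        assert res.coupling_error.max() <= 1e-8
        assert np.abs(res.flux_balance).max() <= cfg.newton_abs_tol


class TestSimulation:
    def test_step_count_is_rounded_ratio(self):
        cfg = SolverConfig(dt=0.01, t_end=14.0)
        assert cfg.n_steps == 1400
        res = run_simulation(None, None, cfg, dry_run=True)
        assert res.step_count == 1400

    def test_rest_without_stimulus_stays_at_rest(self, small_cylinder, balanced_model):
        res = run_simulation(small_cylinder, balanced_model, SolverConfig(dt=0.02, t_end=0.4))
        for tr in res.vm.values():
            assert np.abs(tr).max() < 1e-9
        for tr in res.phi.values():
            assert np.abs(tr).max() < 1e-9

    def test_spike_arrives_later_at_distant_probes(self, stimulated_model):
        """Causality on a cylinder longer than the active wavefront: the
        stimulated end crosses half-amplitude before the midpoint, the
        midpoint before the far end."""
        mesh = build_cylinder_domain(
            2000.0, 200.0, extracellular_margin=300.0, resolution=100.0,
            n_theta=8, axial_resolution=250.0,
        )
        model = MembraneModel(
            params=stimulated_model.params,
            stimuli=[StimulusSpec(cell=0, amplitude=400.0, t_on=0.0, t_off=0.3)],
        )
        res = run_simulation(mesh, model, SolverConfig(dt=0.01, t_end=1.6))
        thr = 0.5 * res.vm["end0"].max()
        t_cross = {
            k: res.times[np.argmax(res.vm[k] >= thr)] for k in ("end0", "mid", "end1")
        }
        assert t_cross["end0"] < t_cross["mid"] < t_cross["end1"]

    def test_flux_splits_into_balanced_source_and_sink(self, small_cylinder, stimulated_model):
        """Mid-upstroke the inward and outward membrane currents are each
        large while their sum stays below the Newton tolerance."""
        flux = {}
        cfg = SolverConfig(dt=0.01, t_end=0.5)
        run_simulation(
            small_cylinder, stimulated_model, cfg,
            state_callback=lambda s, st, info: flux.__setitem__(s, info["flux"].copy()),
        )
        F = flux[max(flux)]
        influx, outflux = F[F < 0].sum(), F[F > 0].sum()
        assert outflux > 1.0 and influx < -1.0
        assert abs(influx + outflux) <= cfg.newton_abs_tol

    def test_sphere_axisymmetric_response(self, small_sphere, stimulated_model):
        """Polar-cap stimulus on the sphere: phi_out is axisymmetric within
        discretization error (values at same polar angle agree)."""
        model = MembraneModel(
            params=stimulated_model.params,
            stimuli=[StimulusSpec(cell=0, amplitude=2.0, t_on=0.0, t_off=0.2)],
        )
        res = run_simulation(small_sphere, model, SolverConfig(dt=0.01, t_end=0.2))
        st = res.final_state
        asm = res.assembly
        pts = small_sphere.vertices[asm.extra_ids]
        r = np.linalg.norm(pts, axis=1)
        shell = np.abs(r - 10.0) < 1e-9  # membrane shell, extracellular side
        cosang = pts[shell, 2] / r[shell]
        band = np.abs(cosang) < 0.35  # equatorial band, same polar angle
        phis = st.phi_out[shell][band]
        assert phis.std() < 0.15 * (np.abs(st.phi_out).max() + 1e-30)

    def test_ephaptic_toggle_decouples_membrane(self, small_cylinder, stimulated_model):
        """With the ephaptic current disabled the membrane problem no longer
        sees the extracellular field: V_m solutions differ between toggles
        while both conserve flux."""
        r_on = run_simulation(small_cylinder, stimulated_model, SolverConfig(dt=0.01, t_end=0.4))
        r_off = run_simulation(
            small_cylinder, stimulated_model, SolverConfig(dt=0.01, t_end=0.4), ephaptic=False
        )
        d = max(
            np.abs(r_on.vm[k] - r_off.vm[k]).max() for k in r_on.vm
        )
        assert d > 0.0
        assert np.abs(r_off.flux_balance).max() <= 1e-6


class TestFluxDensity:
    def test_density_times_area_recovers_flux(self, cylinder_assembly):
        rng = np.random.default_rng(3)
        F = rng.normal(size=len(cylinder_assembly.mem_ids))
        j = membrane_flux_density(cylinder_assembly, F)
        areas = cylinder_assembly.dual.membrane_area_total[cylinder_assembly.mem_ids]
        assert np.allclose(j * areas * 1e-5, F)

    def test_total_flux_per_cell_sums_components(self, cylinder_assembly):
        F = np.ones(len(cylinder_assembly.mem_ids))
        assert total_membrane_flux(cylinder_assembly, F) == pytest.approx(len(F))
        assert total_membrane_flux(cylinder_assembly, F, cell=0) == pytest.approx(len(F))
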