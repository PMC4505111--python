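"""Mesh generators: geometry, labels, invariants, refinement."""

import numpy as np
import pytest

from neurocable3d import (
    NeuronGeometrySpec,
    Patch,
    Subdomain,
    build_cylinder_domain,
    build_network_domain,
    build_parallel_cylinders,
    build_sphere_domain,
    refine_uniform,
)
from neurocable3d.mesh.builders import icosphere
from neurocable3d.mesh.core import tet_volumes, triangle_area_vectors


class TestCylinder:
    def test_intracellular_volume_matches_polygon_prism(self):
        """The INTRA region is an extruded regular n-gon: its volume is the
        inscribed-polygon area (n/2 r^2 sin(2pi/n)) times the length."""
        for n_theta in (8, 16):
            mesh = build_cylinder_domain(
                1000.0, 200.0, extracellular_margin=200.0, resolution=100.0,
                n_theta=n_theta, axial_resolution=250.0,
            )
            expected = 0.5 * n_theta * 100.0**2 * np.sin(2 * np.pi / n_theta) * 1000.0
            assert mesh.subdomain_volume(Subdomain.INTRA) == pytest.approx(expected, rel=1e-12)

    def test_polygon_volume_approaches_circular_cylinder(self):
        """With a fine cross-section the INTRA volume approaches pi r^2 l
        within the polyhedral-approximation deficit (paper cylinder dims)."""
        mesh = build_cylinder_domain(
            9800.0, 200.0, extracellular_margin=200.0, resolution=100.0,
            n_theta=32, axial_resolution=2450.0,
        )
        exact = np.pi * 100.0**2 * 9800.0
        deficit = 1.0 - (32 / (2 * np.pi)) * np.sin(2 * np.pi / 32)
        vol = mesh.subdomain_volume(Subdomain.INTRA)
        assert abs(vol - exact) / exact == pytest.approx(deficit, rel=1e-9)

    def test_membrane_faces_separate_intra_from_extra(self, small_cylinder):
        # validate() checks every membrane triangle is shared by exactly one
        # INTRA and one EXTRA tet and is oriented intra -> extra
        small_cylinder.validate()

    def test_membrane_orientation_points_outward(self, small_cylinder):
        mesh = small_cylinder
        normals = triangle_area_vectors(mesh.vertices, mesh.mem_tris)
        centers = mesh.vertices[mesh.mem_tris].mean(axis=1)
        lateral = np.abs(centers[:, 2] - 200.0) < 199.0  # away from end caps
        radial = centers[lateral][:, :2]
        assert np.all(np.einsum("ij,ij->i", normals[lateral][:, :2], radial) > 0)

    def test_markers_on_axis(self, small_cylinder):
        for name, z in (("end0", 0.0), ("mid", 200.0), ("end1", 400.0)):
            v = small_cylinder.vertices[small_cylinder.markers[name]]
            assert np.hypot(v[0], v[1]) == 0.0 and v[2] == z

    def test_rejects_unresolvable_cross_section(self):
        with pytest.raises(ValueError, match="resolution"):
            build_cylinder_domain(1000.0, 50.0, resolution=80.0)


class TestSphere:
    def test_icosphere_triangle_count(self):
        for s in (0, 1, 2, 3):
            _, faces = icosphere(s)
            assert len(faces) == 20 * 4**s

    def test_membrane_vertices_on_sphere(self, small_sphere):
        r = np.linalg.norm(small_sphere.vertices[small_sphere.membrane_vertices()], axis=1)
        assert np.allclose(r, 10.0, rtol=1e-12)

    def test_membrane_area_approaches_sphere(self):
        areas = []
        for s in (1, 2, 3):
            m = build_sphere_domain(1.0, 2.0, subdivisions=s, resolution=0.5)
            areas.append(m.membrane_area())
        exact = 4.0 * np.pi
        errs = [abs(a - exact) / exact for a in areas]
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.01

    def test_rejects_bad_radii(self):
        with pytest.raises(ValueError, match="radius"):
            build_sphere_domain(10.0, 5.0, resolution=2.0)

    def test_stimulus_cap_labels(self, small_sphere):
        stim = small_sphere.tri_patch == Patch.STIMULUS
        assert stim.any()
        centers = small_sphere.vertices[small_sphere.mem_tris[stim]].mean(axis=1)
        u = centers / np.linalg.norm(centers, axis=1)[:, None]
        assert u[:, 2].min() > np.cos(np.deg2rad(35.0))


class TestNetwork:
    def test_four_cell_network_mirrors_reference_layout(self):
        """Four idealized neurons with a synapse pair connecting distinct
        cells, active somata/nodes, myelin internodes and dendrites."""
        spec = NeuronGeometrySpec(
            soma_diameter=10.0, axon_diameter=4.0, axon_length=24.0,
            dendrite_diameter=6.0, dendrite_length=12.0, node_spacing=8.0,
            node_length=3.0, synapses=((0, 1), (2, 3)), stimulus_cells=(0, 3),
            resolution=2.0, cell_spacing=8.0, extracellular_margin=6.0,
        )
        mesh = build_network_domain(spec, 4)
        mesh.validate()
        assert mesh.n_cells == 4
        labels = set(Patch(p) for p in mesh.tri_patch)
        assert {Patch.DENDRITE, Patch.ACTIVE, Patch.MYELIN, Patch.SYNAPSE_PRE,
                Patch.SYNAPSE_POST, Patch.STIMULUS} <= labels
        pre_cells = set(mesh.tri_cell[mesh.tri_patch == Patch.SYNAPSE_PRE])
        post_cells = set(mesh.tri_cell[mesh.tri_patch == Patch.SYNAPSE_POST])
        assert pre_cells == {0, 2} and post_cells == {1, 3}

    def test_single_cell_has_no_synapse_patches(self):
        spec = NeuronGeometrySpec(
            soma_diameter=10.0, axon_diameter=4.0, axon_length=16.0,
            dendrite_diameter=6.0, dendrite_length=8.0, resolution=2.0,
            extracellular_margin=6.0,
        )
        mesh = build_network_domain(spec, 1)
        assert not np.any(np.isin(mesh.tri_patch, (Patch.SYNAPSE_PRE, Patch.SYNAPSE_POST)))

    def test_two_cell_synapse_sides(self):
        spec = NeuronGeometrySpec(
            soma_diameter=10.0, axon_diameter=4.0, axon_length=16.0,
            dendrite_diameter=6.0, dendrite_length=12.0, synapses=((0, 1),),
            resolution=2.0, cell_spacing=8.0, extracellular_margin=6.0,
        )
        mesh = build_network_domain(spec, 2)
        assert set(mesh.tri_cell[mesh.tri_patch == Patch.SYNAPSE_PRE]) == {0}
        assert set(mesh.tri_cell[mesh.tri_patch == Patch.SYNAPSE_POST]) == {1}

    def test_rejects_same_cell_synapse(self):
        spec = NeuronGeometrySpec(synapses=((1, 1),))
        with pytest.raises(ValueError, match="distinct cells"):
            build_network_domain(spec, 2)

    def test_rejects_touching_cells(self):
        with pytest.raises(ValueError, match="overlap"):
            build_parallel_cylinders(2, length=16.0, diameter=6.0, gap=0.5,
                                     margin=4.0, resolution=2.0)


class TestRefinement:
    def test_uniform_refinement_octuples_tets_and_preserves_measure(self, small_cylinder):
        fine = refine_uniform(small_cylinder)
        fine.validate()
        assert fine.n_tets == 8 * small_cylinder.n_tets
        for sub in (Subdomain.INTRA, Subdomain.EXTRA):
            v0 = small_cylinder.subdomain_volume(sub)
            assert abs(fine.subdomain_volume(sub) - v0) / v0 < 1e-10
        a0 = small_cylinder.membrane_area()
        assert abs(fine.membrane_area() - a0) / a0 < 1e-10
        assert len(fine.mem_tris) == 4 * len(small_cylinder.mem_tris)

    def test_children_positively_oriented(self, small_sphere):
        fine = refine_uniform(small_sphere)
        assert tet_volumes(fine.vertices, fine.tets).min() > 0
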