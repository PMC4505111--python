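"""Shared fixtures: small deterministic meshes reused across test modules."""

import numpy as np
import pytest

from neurocable3d import (
    HHParameters,
    MembraneModel,
    StimulusSpec,
    build_assembly,
    build_cylinder_domain,
    build_sphere_domain,
    e_l_for_rest,
)


@pytest.fixture(scope="session")
def small_cylinder():
    """Short active cylinder: 400 um long, 100 um diameter, coarse."""
    mesh = build_cylinder_domain(
        400.0, 100.0, extracellular_margin=100.0, resolution=50.0,
        n_theta=8, axial_resolution=100.0,
    )
    mesh.validate()
    return mesh


@pytest.fixture(scope="session")
def small_sphere():
    """Spherical cell of radius 10 um with a polar stimulus cap."""
    mesh = build_sphere_domain(
        10.0, 30.0, resolution=5.0, subdivisions=2,
        stimulus_direction=(0.0, 0.0, 1.0), stimulus_angle_deg=25.0,
    )
    mesh.validate()
    return mesh


@pytest.fixture(scope="session")
def cylinder_assembly(small_cylinder):
    return build_assembly(small_cylinder, 2.0, 20.0)


@pytest.fixture()
def balanced_model():
    """HH membrane with the leak reversal balancing the rest state."""
    return MembraneModel(params=e_l_for_rest(HHParameters()))


@pytest.fixture()
def stimulated_model():
    return MembraneModel(
        params=e_l_for_rest(HHParameters()),
        stimuli=[StimulusSpec(cell=0, amplitude=80.0, t_on=0.0, t_off=0.3)],
    )
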