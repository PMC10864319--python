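"""Shared fixtures: geometries, operating conditions, synthetic fields.

Session scope is used for the expensive objects (volume-matched
distributions, full-grid extractions) so that the many assertions made
against them do not rebuild them.
"""

import numpy as np
import pytest

from shakeflask import (
    FlaskDimensions,
    FlaskGeometry,
    FluidProperties,
    OperatingCondition,
    extract_contact_lines,
    solve_fill,
)
from shakeflask.synthetic import SyntheticSpec, generate_alpha_field


@pytest.fixture(scope="session")
def dims():
    return FlaskDimensions()


@pytest.fixture(scope="session")
def smooth_geom(dims):
    return FlaskGeometry(dims, "smooth")


@pytest.fixture(scope="session")
def sharp_geom(dims):
    return FlaskGeometry(dims, "sharp")


@pytest.fixture(scope="session")
def cond_250_40():
    """40 mL at 250 rpm on a 2.5 cm orbit — the reference condition."""
    return OperatingCondition.from_rpm(250.0, 0.025, 40.0)


@pytest.fixture(scope="session")
def water():
    return FluidProperties()


@pytest.fixture(scope="session")
def reference_distribution(smooth_geom, cond_250_40):
    return solve_fill(smooth_geom, cond_250_40)


@pytest.fixture(scope="session")
def plain_synthetic_field(smooth_geom, cond_250_40):
    """No film, no phase shift: the mechanistic bulk as a VOF field."""
    spec = SyntheticSpec(geometry=smooth_geom, condition=cond_250_40)
    return generate_alpha_field(spec)


@pytest.fixture(scope="session")
def film_synthetic_field(smooth_geom, cond_250_40):
    """500 µm wall film up to the bulk maximal height."""
    spec = SyntheticSpec(geometry=smooth_geom, condition=cond_250_40,
                         film_thickness_um=500.0)
    return generate_alpha_field(spec)


@pytest.fixture(scope="session")
def film_contact_lines(film_synthetic_field):
    return extract_contact_lines(film_synthetic_field)


@pytest.fixture(scope="session")
def coarse_mesh_kwargs():
    """Mesh resolution used for dissipation tests: coarse but >= 20 cells
    across the diameter, with 100 µm wall layers resolving the film."""
    return dict(n_radial=12, n_wall_layers=10, n_azimuth=36, z_cell_mm=2.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240213)
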