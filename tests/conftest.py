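import numpy as np
import pytest

from pjaplan import (
    DiscGeometryParams,
    LoadCase,
    MaterialParams,
    assemble_and_solve,
    build_disc_mesh,
    summarize_stress,
)


@pytest.fixture(scope="session")
def default_params():
    return DiscGeometryParams()


@pytest.fixture(scope="session")
def default_mesh(default_params):
    return build_disc_mesh(default_params)


@pytest.fixture(scope="session")
def disc_materials():
    return MaterialParams.disc_defaults()


@pytest.fixture(scope="session")
def single_material():
    """One homogeneous material with nu = 0: closed-form uniaxial behaviour."""
    return MaterialParams(
        young_modulus={"annulus": 1.0, "nucleus": 1.0},
        poisson_ratio={"annulus": 0.0, "nucleus": 0.0},
    )


@pytest.fixture(scope="session")
def solved_case(default_mesh, disc_materials):
    """One representative load case (G = 240 N, alpha = 10 deg) solved once."""
    load = LoadCase(gravity_force_G=240.0, pja_alpha_deg=10.0)
    return load, assemble_and_solve(default_mesh, disc_materials, load)


@pytest.fixture(scope="session")
def unit_summary(default_mesh, disc_materials):
    sol = assemble_and_solve(default_mesh, disc_materials,
                             LoadCase(gravity_force_G=1.0, pja_alpha_deg=0.0))
    return summarize_stress(sol, default_mesh)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
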