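"""Loading model, element stiffness, global solves, stress recovery."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pjaplan import (
    LoadCase,
    MaterialParams,
    assemble_and_solve,
    body_weight_to_G,
    build_disc_mesh,
    compute_loading_force,
    element_stiffness,
    summarize_stress,
    von_mises,
)

TET = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])


class TestLoadingForce:
    def test_worked_values(self):
        assert compute_loading_force(100.0, 0.0) == pytest.approx(100.0)
        assert compute_loading_force(200.0, 60.0) == pytest.approx(100.0)
        assert compute_loading_force(300.0, 8.4) == pytest.approx(
            300.0 * np.cos(np.deg2rad(8.4)), rel=1e-12)

    @given(st.floats(0.0, 89.0), st.floats(0.0, 88.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_monotone_decreasing_in_angle(self, a, delta):
        b = min(a + delta + 1e-6, 89.999)
        assert compute_loading_force(100.0, b) < compute_loading_force(100.0, a)

    @pytest.mark.parametrize("G,alpha", [(-1.0, 10.0), (100.0, 90.0), (100.0, -0.1)])
    def test_rejects_out_of_range(self, G, alpha):
        with pytest.raises(ValueError):
            compute_loading_force(G, alpha)

    def test_body_weight_to_G(self):
        assert body_weight_to_G(49.0, 0.5) == pytest.approx(240.345)
        assert body_weight_to_G(70.0, 1.0) == pytest.approx(70.0 * 9.81)
        ratio = body_weight_to_G(32.5, 0.5) / body_weight_to_G(71.0, 0.5)
        assert ratio == pytest.approx(32.5 / 71.0)
        with pytest.raises(ValueError):
            body_weight_to_G(0.0)


class TestElementStiffness:
    def test_symmetric(self):
        K = element_stiffness(TET, E=2.0, nu=0.3)
        assert np.allclose(K, K.T, atol=1e-14)

    def test_rigid_body_modes_carry_no_energy(self):
        K = element_stiffness(TET, E=2.0, nu=0.3)
        # three translations
        for d in range(3):
            u = np.zeros(12)
            u[d::3] = 1.0
            assert np.abs(K @ u).max() < 1e-12
        # three infinitesimal rotations u = omega x r
        for omega in np.eye(3):
            u = np.cross(omega, TET).ravel()
            assert np.abs(K @ u).max() < 1e-12
        assert np.linalg.matrix_rank(K, tol=1e-10) == 6

    def test_uniaxial_strain_energy_matches_closed_form(self):
        E, eps = 3.0, 0.01
        K = element_stiffness(TET, E=E, nu=0.0)
        u = np.zeros((4, 3))
        u[:, 2] = eps * TET[:, 2]
        energy = 0.5 * u.ravel() @ K @ u.ravel()
        vol = 1.0 / 6.0
        assert energy == pytest.approx(0.5 * vol * E * eps**2, rel=1e-12)

    def test_degenerate_tet_rejected(self):
        flat = TET.copy()
        flat[3] = [0.5, 0.5, 0.0]
        with pytest.raises(ValueError):
            element_stiffness(flat, E=1.0, nu=0.3)


class TestVonMises:
    def test_hydrostatic_is_zero(self):
        assert von_mises(2.5 * np.eye(3)) == pytest.approx(0.0, abs=1e-12)

    def test_uniaxial_magnitude(self):
        assert von_mises(np.diag([-3.0, 0.0, 0.0])) == pytest.approx(3.0)

    def test_matches_eigenvalue_formula_on_random_tensors(self, rng):
        for _ in range(20):
            A = rng.normal(size=(3, 3))
            S = (A + A.T) / 2
            lam = np.linalg.eigvalsh(S)
            expected = np.sqrt(((lam[0] - lam[1]) ** 2 + (lam[1] - lam[2]) ** 2
                                + (lam[2] - lam[0]) ** 2) / 2.0)
            assert von_mises(S) == pytest.approx(expected, rel=1e-12)

    def test_rotation_invariance(self, rng):
        A = rng.normal(size=(3, 3))
        S = (A + A.T) / 2
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert von_mises(Q @ S @ Q.T) == pytest.approx(float(von_mises(S)), rel=1e-10)


class TestGlobalSolve:
    def test_patch_test_uniform_compression(self, default_mesh, single_material):
        """With nu = 0 and a uniform top pressure the exact solution is a
        homogeneous uniaxial stress state, which constant-strain tets must
        reproduce to solver precision."""
        p = 0.1  # MPa
        height = 8.0
        area = default_mesh.element_volumes().sum() / height
        sol = assemble_and_solve(default_mesh, single_material,
                                 LoadCase(gravity_force_G=p * area, pja_alpha_deg=0.0))
        expected = np.diag([0.0, 0.0, -p])
        assert np.abs(sol.stress_tensor - expected).max() < 1e-8 * p
        uz = sol.displacements[default_mesh.superior_nodes, 2]
        assert np.allclose(uz, -p * height / 1.0, rtol=1e-8)

    def test_reactions_balance_applied_load(self, default_mesh, solved_case):
        load, sol = solved_case
        assert sol.reactions[:, 2].sum() == pytest.approx(load.force, rel=1e-9)
        assert abs(sol.reactions[:, 0].sum()) < 1e-9 * load.force
        fixed = np.zeros(default_mesh.n_nodes, dtype=bool)
        fixed[default_mesh.inferior_nodes] = True
        assert np.abs(sol.displacements[fixed]).max() == 0.0

    def test_linearity_in_load(self, default_mesh, disc_materials, solved_case):
        load, sol = solved_case
        double = assemble_and_solve(
            default_mesh, disc_materials,
            LoadCase(gravity_force_G=2 * load.gravity_force_G,
                     pja_alpha_deg=load.pja_alpha_deg))
        assert np.allclose(double.displacements, 2 * sol.displacements, rtol=1e-9)
        assert np.allclose(double.von_mises, 2 * sol.von_mises, rtol=1e-9)

    def test_left_right_symmetry_of_stress_summaries(self, default_mesh, solved_case):
        """Symmetric geometry + axial load: L and R subregion summaries agree
        up to discretization (the tet diagonals are not mirror-symmetric, so
        the discrete stress field is only approximately symmetric)."""
        _, sol = solved_case
        s = summarize_stress(sol, default_mesh)
        for i, j in [(0, 1), (2, 3), (4, 5), (6, 7)]:  # *-L vs *-R pairs
            assert s.max_stress[i] == pytest.approx(s.max_stress[j], rel=0.05)
            assert s.avg_stress[i] == pytest.approx(s.avg_stress[j], rel=0.05)

    def test_unconstrained_mesh_rejected(self, default_mesh, disc_materials):
        free = dataclasses.replace(default_mesh, inferior_nodes=np.array([], dtype=int))
        with pytest.raises(ValueError, match="singular"):
            assemble_and_solve(free, disc_materials, LoadCase(100.0, 0.0))

    def test_missing_material_rejected(self, default_mesh):
        mats = MaterialParams(young_modulus={"annulus": 3.4},
                              poisson_ratio={"annulus": 0.45})
        with pytest.raises(ValueError, match="nucleus"):
            assemble_and_solve(default_mesh, mats, LoadCase(100.0, 0.0))


def test_nearly_incompressible_nucleus_accepted():
    MaterialParams(young_modulus={"nucleus": 1.0}, poisson_ratio={"nucleus": 0.49})
    with pytest.raises(ValueError):
        MaterialParams(young_modulus={"nucleus": 1.0}, poisson_ratio={"nucleus": 0.5})
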