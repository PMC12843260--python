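"""Mooney-Rivlin membrane: closed forms, FEM solver, postprocessing."""

import numpy as np
import pytest

from cytostretch.membrane_mechanics import (
    BoundaryCondition,
    DeformationState,
    MooneyRivlinMaterial,
    build_membrane_mesh,
    central_region_uniformity,
    evaluate_field,
    internal_force,
    solve_plane_stress,
    strain_energy,
    total_strain_energy,
    uniaxial_stress,
    uniaxial_stretch_bc,
    von_mises,
    write_vtk,
)

MAT = MooneyRivlinMaterial(C10=0.12, C01=0.03)


class TestClosedForms:
    def test_undeformed_state_has_zero_energy(self):
        state = DeformationState.from_F(np.eye(2))
        assert state.I1 == pytest.approx(3.0)
        assert state.I2 == pytest.approx(3.0)
        assert strain_energy(state, MAT) == pytest.approx(0.0)

    def test_uniaxial_energy_at_ten_percent_stretch(self):
        # incompressible uniaxial: F = diag(lam, 1/sqrt(lam))
        lam = 1.1
        state = DeformationState.from_F(np.diag([lam, 1.0 / np.sqrt(lam)]))
        assert state.I1 == pytest.approx(lam**2 + 2.0 / lam)
        assert state.I2 == pytest.approx(2.0 * lam + 1.0 / lam**2)
        assert strain_energy(state, MAT) == pytest.approx(0.0041752, abs=1e-6)

    def test_energy_monotone_on_uniaxial_path(self):
        lams = np.linspace(1.0, 1.5, 20)
        ws = [strain_energy(
            DeformationState.from_F(np.diag([l, 1 / np.sqrt(l)])), MAT)
            for l in lams]
        assert np.all(np.diff(ws) > 0)

    def test_invalid_invariants_rejected(self):
        bad = DeformationState(F=np.eye(2), lambda3=1.0, I1=2.5, I2=3.0)
        with pytest.raises(ValueError):
            strain_energy(bad, MAT)

    def test_uniaxial_stress_values(self):
        assert uniaxial_stress(1.0, MAT) == pytest.approx(0.0)
        assert uniaxial_stress(1.1, MAT) == pytest.approx(0.0886314, abs=1e-6)
        with pytest.raises(ValueError):
            uniaxial_stress(-1.0, MAT)

    def test_small_strain_modulus_is_six_times_coefficient_sum(self):
        h = 1e-6
        slope = (uniaxial_stress(1 + h, MAT) - uniaxial_stress(1 - h, MAT)) / (2 * h)
        assert slope == pytest.approx(6.0 * (MAT.C10 + MAT.C01), rel=0.01)

    def test_stress_is_energy_derivative_along_uniaxial_path(self):
        # nominal stress dW/dlam equals sigma/lam for the incompressible path
        lam, h = 1.23, 1e-6

        def w(l):
            return strain_energy(
                DeformationState.from_F(np.diag([l, 1 / np.sqrt(l)])), MAT)

        dw = (w(lam + h) - w(lam - h)) / (2 * h)
        assert dw == pytest.approx(uniaxial_stress(lam, MAT) / lam, rel=1e-5)


class TestMesh:
    def test_node_and_element_counts(self):
        mesh = build_membrane_mesh(30, 10, 1, 60, 20)
        assert mesh.quad_elements.shape[0] == 1200
        assert mesh.node_coordinates.shape[0] == 1281

    def test_total_area_conserved(self):
        mesh = build_membrane_mesh(30, 10, 1, 7, 5)
        X = mesh.node_coordinates[mesh.quad_elements]
        # shoelace per quad
        x, y = X[:, :, 0], X[:, :, 1]
        area = 0.5 * np.abs(
            np.sum(x * np.roll(y, -1, axis=1) - np.roll(x, -1, axis=1) * y, axis=1))
        assert area.sum() == pytest.approx(300.0)

    def test_too_coarse_mesh_rejected(self):
        with pytest.raises(ValueError):
            build_membrane_mesh(30, 10, 1, 1, 5)
        with pytest.raises(ValueError):
            build_membrane_mesh(-1, 10, 1, 4, 4)

    def test_high_aspect_ratio_warns(self):
        with pytest.warns(UserWarning, match="aspect"):
            build_membrane_mesh(30, 10, 1, 60, 2)


class TestSolver:
    def test_zero_displacement_gives_zero_fields(self):
        mesh = build_membrane_mesh(10, 5, 1, 4, 2)
        field = solve_plane_stress(mesh, MAT, uniaxial_stretch_bc(mesh, 0.0))
        np.testing.assert_allclose(field.principal_strains, 0.0, atol=1e-12)
        np.testing.assert_allclose(field.von_mises_stress, 0.0, atol=1e-12)

    def test_single_element_matches_closed_form(self):
        mesh = build_membrane_mesh(1, 1, 1, 2, 2)
        bc = uniaxial_stretch_bc(mesh, 0.1, grip=False)
        field = solve_plane_stress(mesh, MAT, bc)
        expected = uniaxial_stress(1.1, MAT)
        np.testing.assert_allclose(field.cauchy_stress[:, 0, 0], expected,
                                   rtol=1e-6)
        np.testing.assert_allclose(field.cauchy_stress[:, 1, 1], 0.0, atol=1e-10)

    def test_disjoint_edge_invariant_enforced(self):
        with pytest.raises(ValueError):
            BoundaryCondition(np.array([0]), np.array([0.0]),
                              fixed_edge_nodes=np.array([1, 2]),
                              displaced_edge_nodes=np.array([2, 3]))

    def test_energy_gradient_consistency(self):
        """Internal force equals the finite-difference gradient of the energy."""
        mesh = build_membrane_mesh(2, 2, 1, 2, 2)
        rng = np.random.default_rng(42)
        u = 0.02 * rng.normal(size=2 * mesh.node_coordinates.shape[0])
        f = internal_force(mesh, MAT, u)
        h = 1e-6
        g = np.empty_like(f)
        for k in range(u.size):
            up, um = u.copy(), u.copy()
            up[k] += h
            um[k] -= h
            g[k] = (total_strain_energy(mesh, MAT, up)
                    - total_strain_energy(mesh, MAT, um)) / (2 * h)
        np.testing.assert_allclose(f, g, rtol=1e-5, atol=1e-10 * np.abs(f).max())

    def test_objectivity_under_rigid_rotation(self):
        """Rotating a converged deformation leaves invariant measures unchanged."""
        mesh = build_membrane_mesh(10, 5, 1, 8, 4)
        field = solve_plane_stress(mesh, MAT, uniaxial_stretch_bc(mesh, 1.0))
        u = field.nodal_displacements
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        X = mesh.node_coordinates
        u_rot = (X + u) @ R.T - X
        rotated = evaluate_field(mesh, MAT, u_rot.ravel())
        np.testing.assert_allclose(rotated.principal_strains,
                                   field.principal_strains, atol=1e-8)
        np.testing.assert_allclose(rotated.von_mises_stress,
                                   field.von_mises_stress, atol=1e-8)
        assert total_strain_energy(mesh, MAT, u_rot.ravel()) == pytest.approx(
            total_strain_energy(mesh, MAT, u.ravel()), abs=1e-8)

    def test_incompressibility_at_quadrature_points(self):
        mesh = build_membrane_mesh(10, 5, 1, 8, 4)
        field = solve_plane_stress(mesh, MAT, uniaxial_stretch_bc(mesh, 1.0))
        J = np.linalg.det(field.quad_point_F)
        lam3 = 1.0 / J
        np.testing.assert_allclose(J * lam3, 1.0, atol=1e-10)
        assert np.all(J > 0)


class TestPostprocessing:
    def test_von_mises_closed_forms(self):
        mesh = build_membrane_mesh(2, 2, 1, 2, 2)
        field = solve_plane_stress(mesh, MAT, uniaxial_stretch_bc(mesh, 0.0))
        # overwrite stresses with crafted states
        field.cauchy_stress[:] = 0.0
        field.cauchy_stress[:, 0, 0] = 0.5
        np.testing.assert_allclose(von_mises(field), 0.5)
        field.cauchy_stress[:] = 0.0
        field.cauchy_stress[:, 0, 1] = field.cauchy_stress[:, 1, 0] = 0.2
        np.testing.assert_allclose(von_mises(field), np.sqrt(3.0) * 0.2)

    def test_stress_concentration_near_clamped_edges(self):
        mesh = build_membrane_mesh(30, 10, 1, 30, 10)
        field = solve_plane_stress(mesh, MAT, uniaxial_stretch_bc(mesh, 3.0))
        idx = int(np.argmax(field.von_mises_stress))
        x = field.element_centroids[idx, 0]
        assert min(x, 30.0 - x) < 0.1 * 30.0

    def test_uniform_stretch_has_zero_strain_spread(self):
        mesh = build_membrane_mesh(10, 5, 1, 6, 4)
        bc = uniaxial_stretch_bc(mesh, 1.0, grip=False)
        field = solve_plane_stress(mesh, MAT, bc)
        rep = central_region_uniformity(field)
        assert rep.sd_max_principal_engineering_strain == pytest.approx(0.0, abs=1e-9)
        assert rep.mean_max_principal_engineering_strain == pytest.approx(0.1, rel=1e-6)

    def test_central_region_uniformity_at_ten_percent(self):
        mesh = build_membrane_mesh(30, 10, 1, 30, 10)
        field = solve_plane_stress(mesh, MAT, uniaxial_stretch_bc(mesh, 3.0))
        rep = central_region_uniformity(field)
        assert rep.mean_max_principal_engineering_strain == pytest.approx(0.10,
                                                                          rel=0.05)
        assert (rep.sd_max_principal_engineering_strain
                / rep.mean_max_principal_engineering_strain) <= 0.05

    def test_bad_fraction_rejected(self):
        mesh = build_membrane_mesh(10, 5, 1, 6, 4)
        field = solve_plane_stress(mesh, MAT, uniaxial_stretch_bc(mesh, 0.0))
        with pytest.raises(ValueError):
            central_region_uniformity(field, fraction=1.5)

    def test_vtk_export_is_readable_text(self, tmp_path):
        mesh = build_membrane_mesh(10, 5, 1, 4, 2)
        field = solve_plane_stress(mesh, MAT, uniaxial_stretch_bc(mesh, 0.5))
        p = tmp_path / "membrane.vtk"
        write_vtk(field, p)
        text = p.read_text()
        assert text.startswith("# vtk DataFile")
        assert "von_mises_MPa" in text
        assert f"POINTS {mesh.node_coordinates.shape[0]}" in text
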