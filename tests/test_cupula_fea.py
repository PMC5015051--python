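"""Plate finite elements: meshing, MITC accuracy, stiffness, transfer."""

from __future__ import annotations

import numpy as np
import pytest

from semiduct.cupula_fea import (
    SHEAR_CORRECTION,
    CupulaCrossSection,
    CupulaModel,
    GeometryError,
    PlateSolution,
    band_deflection_angle,
    cilia_transfer_factor,
    cupula_stiffness,
    kirchhoff_disc_center_deflection,
    kirchhoff_disc_volume,
    mesh_cross_section,
    mindlin_disc_deflection,
    mindlin_disc_volume,
    solve_plate,
    volume_displacement,
)

from conftest import disc_outline


def _thin_model(nu=0.3):
    return CupulaModel(CupulaCrossSection(disc_outline(0.5)), 0.005, gamma=1.44, nu=nu)


def _thick_model():
    return CupulaModel(CupulaCrossSection(disc_outline(0.5)), 0.25, gamma=1.44, nu=0.48)


class TestMesher:
    def test_disc_mesh_statistics(self):
        mesh = mesh_cross_section(CupulaCrossSection(disc_outline(0.5)), 0.05)
        assert 300 <= len(mesh.quads) <= 1500
        assert mesh.min_angle_deg() >= 20.0
        assert set(np.unique(mesh.strip)) == {-1, 0, 1, 2}

    def test_no_element_straddles_band_borders(self):
        """Every band element lies wholly between two consecutive offsets."""
        mesh = mesh_cross_section(CupulaCrossSection(disc_outline(0.5)), 0.05)
        radii = np.linalg.norm(mesh.nodes, axis=1)
        bands = (0.0,) + mesh.band_heights  # offsets from the outline (r = 0.5)
        # the 720-gon outline radius is within 5e-6 of the true circle
        for strip, (lo, hi) in enumerate(zip(bands[:-1], bands[1:])):
            el = mesh.quads[mesh.strip == strip]
            r_el = radii[el]
            assert np.all(r_el >= 0.5 - hi - 1e-5)
            assert np.all(r_el <= 0.5 - lo + 1e-5)

    def test_band_area_matches_annulus(self):
        mesh = mesh_cross_section(CupulaCrossSection(disc_outline(0.5)), 0.04)
        sol = PlateSolution(mesh, np.zeros(len(mesh.nodes)), np.zeros((len(mesh.nodes), 2)), 0.0)
        from semiduct.cupula_fea import _integrate_w

        for ell in (0.03, 0.06, 0.09):
            _, area = _integrate_w(sol, mesh.band_elements(ell))
            expected = np.pi * (0.5**2 - (0.5 - ell) ** 2)
            assert area == pytest.approx(expected, rel=3e-3)

    def test_self_intersecting_polygon_rejected(self):
        bow = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float)
        with pytest.raises(GeometryError):
            CupulaCrossSection(bow)

    def test_refinement_convergence(self):
        """Halving the target size changes dV by < 0.5 %."""
        q = 0.05
        model = _thick_model()
        dv = []
        for ts in (0.04, 0.02):
            model.mesh = None
            sol = solve_plate(model, q, target_size=ts)
            dv.append(volume_displacement(sol))
        assert abs(dv[1] / dv[0] - 1.0) < 5e-3


class TestMitc4Accuracy:
    def test_thin_limit_matches_kirchhoff(self):
        model = _thin_model()
        q = 0.05
        sol = solve_plate(model, q, target_size=0.04)
        d = model.bending_rigidity
        centre = int(np.argmin(np.linalg.norm(sol.mesh.nodes, axis=1)))
        assert sol.w[centre] == pytest.approx(
            kirchhoff_disc_center_deflection(q, 0.5, d), rel=1e-2
        )
        assert volume_displacement(sol) == pytest.approx(
            kirchhoff_disc_volume(q, 0.5, d), rel=1e-2
        )

    def test_thick_plate_matches_exact_mindlin(self):
        """Transverse shear dominates at h/a = 0.5; the axisymmetric
        Mindlin closed form is the oracle."""
        model = _thick_model()
        q = 0.05
        sol = solve_plate(model, q, target_size=0.03)
        ds = SHEAR_CORRECTION * model.gamma * model.thickness
        ref = mindlin_disc_volume(q, 0.5, model.bending_rigidity, ds)
        assert volume_displacement(sol) == pytest.approx(ref, rel=1e-2)

    def test_naive_integration_locks(self):
        """Without the MITC interpolation the thin plate locks badly."""
        q = 0.05
        ref = kirchhoff_disc_volume(q, 0.5, _thin_model().bending_rigidity)
        sol = solve_plate(_thin_model(), q, mitc=False, target_size=0.05)
        assert volume_displacement(sol) < 0.9 * ref  # err > 10 %

    def test_mitc3_triangles_agree(self):
        model = _thick_model()
        q = 0.05
        sol = solve_plate(model, q, element="mitc3", target_size=0.03)
        ds = SHEAR_CORRECTION * model.gamma * model.thickness
        ref = mindlin_disc_volume(q, 0.5, model.bending_rigidity, ds)
        assert volume_displacement(sol) == pytest.approx(ref, rel=2e-2)

    def test_zero_pressure_zero_field(self):
        sol = solve_plate(_thick_model(), 0.0, target_size=0.06)
        assert np.allclose(sol.w, 0.0)
        assert np.allclose(sol.theta, 0.0)

    def test_linearity_in_pressure_and_modulus(self):
        m1 = _thick_model()
        s1 = solve_plate(m1, 0.05, target_size=0.05)
        s2 = solve_plate(m1, 0.10, target_size=0.05)
        assert np.allclose(s2.w, 2.0 * s1.w, rtol=1e-9, atol=1e-14)
        m2 = CupulaModel(m1.section, m1.thickness, gamma=2 * m1.gamma, nu=m1.nu)
        s3 = solve_plate(m2, 0.05, target_size=0.05)
        assert np.allclose(s3.w, 0.5 * s1.w, rtol=1e-9, atol=1e-14)

    def test_clamped_boundary(self):
        sol = solve_plate(_thick_model(), 0.05, target_size=0.05)
        b = sol.mesh.boundary_nodes
        assert np.allclose(sol.w[b], 0.0)
        assert np.allclose(sol.theta[b], 0.0)
        assert np.all(sol.w[np.setdiff1d(np.arange(len(sol.w)), b)] > 0)


class TestStiffnessAndTransfer:
    def test_stiffness_unit_chain(self):
        # Pa over mm^3 is already g s^-2 mm^-4: 0.05 / 4.35e-6 = 11.5e3?
        # no -- 0.05 Pa / 4.348e-3 mm^3 = 11.5, the printed human scale
        assert cupula_stiffness(0.05, 0.05 / 11.5) == pytest.approx(11.5)

    def test_stiffness_proportional_to_shear_modulus(self):
        q = 0.05
        m1 = _thick_model()
        k1 = cupula_stiffness(q, volume_displacement(solve_plate(m1, q, target_size=0.05)))
        m2 = CupulaModel(m1.section, m1.thickness, gamma=2 * m1.gamma, nu=m1.nu)
        k2 = cupula_stiffness(q, volume_displacement(solve_plate(m2, q, target_size=0.05)))
        assert k2 == pytest.approx(2 * k1, rel=1e-9)

    def test_rigid_translation_band_angle(self):
        """A uniform w field in the band gives exactly arctan(w0/l)."""
        mesh = mesh_cross_section(CupulaCrossSection(disc_outline(0.5)), 0.05)
        w0 = 0.01
        sol = PlateSolution(
            mesh, np.full(len(mesh.nodes), w0), np.zeros((len(mesh.nodes), 2)), 0.05
        )
        for ell in (0.03, 0.06, 0.09):
            assert band_deflection_angle(sol, ell) == pytest.approx(
                np.arctan(w0 / ell), rel=1e-12
            )

    def test_transfer_factor_pressure_invariant(self):
        m = _thick_model()
        e1 = cilia_transfer_factor(solve_plate(m, 0.05, target_size=0.05), 0.06)
        m.mesh = None
        e2 = cilia_transfer_factor(solve_plate(m, 0.005, target_size=0.05), 0.06)
        assert e1 == pytest.approx(e2, rel=1e-3)

    def test_band_angles_match_closed_form_profile(self):
        """FEA band means vs quadrature of the exact Mindlin profile.

        Two independent routes to dTheta(l); both show the same weak
        increase with cilia length (the band mean of w grows slightly
        faster than linearly in the band height next to the clamp).
        """
        from scipy.integrate import quad

        model = _thick_model()
        q = 0.05
        sol = solve_plate(model, q, target_size=0.03)
        d = model.bending_rigidity
        ds = SHEAR_CORRECTION * model.gamma * model.thickness
        angles = []
        for ell in (0.03, 0.06, 0.09):
            num = quad(
                lambda r: np.arctan(mindlin_disc_deflection(r, q, 0.5, d, ds) / ell)
                * 2 * np.pi * r,
                0.5 - ell,
                0.5,
            )[0]
            oracle = num / (np.pi * (0.5**2 - (0.5 - ell) ** 2))
            fea = band_deflection_angle(sol, ell)
            assert fea == pytest.approx(oracle, rel=2e-2)
            angles.append(oracle)
        assert angles[0] < angles[1] < angles[2]  # oracle-verified direction

    def test_unknown_band_rejected(self):
        sol = solve_plate(_thick_model(), 0.05, target_size=0.06)
        with pytest.raises(ValueError, match="cilia length"):
            band_deflection_angle(sol, 0.045)


def test_vtk_export_round_numbers(tmp_path):
    from semiduct.cupula_fea import export_solution_vtk

    sol = solve_plate(_thick_model(), 0.05, target_size=0.08)
    p = tmp_path / "field.vtk"
    export_solution_vtk(sol, p)
    text = p.read_text().splitlines()
    assert text[0].startswith("# vtk")
    assert any(line.startswith("POINTS") for line in text)
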