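"""Morphometric quantities: tube statistics, circuits, coefficients."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import quad

from semiduct.constants import PhysiologyConstants
from semiduct.morphometry import (
    CIRCLE_DRAG,
    ConnectivityError,
    area_variation_to_offset,
    circuit_streamline,
    circuit_vector_area,
    damping_coefficient,
    drag_factor,
    ellipse_from_area_perimeter,
    g_vector,
    inertia_coefficient,
    part_morphometry,
    polyline_length,
    radius_of_curvature,
    ramanujan_perimeter,
)


class TestPolylineLength:
    def test_unit_segment(self):
        assert polyline_length(np.array([[0, 0, 0], [1, 0, 0]])) == 1.0

    def test_circle_polygon(self):
        t = np.linspace(0, 2 * np.pi, 361)
        pts = 3.0 * np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
        assert polyline_length(pts) == pytest.approx(2 * np.pi * 3.0, rel=1e-4)

    def test_repeated_point_warns(self):
        with pytest.warns(UserWarning, match="zero length"):
            assert polyline_length(np.zeros((2, 3))) == 0.0


class TestEllipseRecovery:
    def test_circular_tube_limit(self):
        L, r = 10.0, 0.1
        pm = part_morphometry("t", np.pi * r**2 * L, 2 * np.pi * r * L, L)
        assert pm.semi_major == pytest.approx(r, rel=1e-9)
        assert pm.semi_minor == pytest.approx(r, rel=1e-9)
        assert pm.drag_factor == pytest.approx(CIRCLE_DRAG, rel=1e-9)

    def test_elliptic_forward_inverse_round_trip(self):
        a_ax, b_ax = 0.2, 0.05
        area = np.pi * a_ax * b_ax
        perim = ramanujan_perimeter(a_ax, b_ax)
        ra, rb = ellipse_from_area_perimeter(area, perim)
        assert ra == pytest.approx(a_ax, abs=1e-4)
        assert rb == pytest.approx(b_ax, abs=1e-4)
        assert drag_factor(ra, rb) == pytest.approx(
            4 * np.pi * (a_ax**2 + b_ax**2) / (a_ax * b_ax), rel=1e-4
        )
        # spec anchor: this ellipse has drag factor 53.41
        assert drag_factor(a_ax, b_ax) == pytest.approx(53.407, abs=5e-3)

    def test_impossible_perimeter_clamps_to_circle(self):
        area = np.pi * 0.01
        with pytest.warns(UserWarning, match="circular minimum"):
            ra, rb = ellipse_from_area_perimeter(area, 0.5 * 2 * np.pi * 0.1)
        assert ra == rb == pytest.approx(0.1)

    @pytest.mark.parametrize("ratio", [1.0, 0.7, 0.3, 0.1, 0.02])
    def test_drag_factor_properties(self, ratio):
        a_ax = 0.2
        b_ax = ratio * a_ax
        lam = drag_factor(a_ax, b_ax)
        assert lam >= CIRCLE_DRAG - 1e-12
        assert lam == pytest.approx(drag_factor(b_ax, a_ax))  # symmetry
        if ratio < 1.0:
            assert lam > drag_factor(a_ax, (ratio + 0.01) * a_ax)  # monotone


class TestVectorAreaAndG:
    def test_unit_square(self):
        loop = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 0]], float)
        assert np.allclose(circuit_vector_area(loop), [0, 0, 1.0])

    def test_planar_circle_and_origin_invariance(self):
        t = np.linspace(0, 2 * np.pi, 361)
        loop = 3.0 * np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
        a1 = circuit_vector_area(loop)
        assert np.linalg.norm(a1) == pytest.approx(9 * np.pi, rel=5e-4)
        a2 = circuit_vector_area(loop + np.array([100.0, 0, 0]))
        assert np.allclose(a1, a2, atol=1e-8)

    def test_g_magnitude_matches_human_lateral_duct(self):
        # a circle of radius 3.615 mm at water density gives |g| = 82.1,
        # the printed human lateral-duct value (consistent with R ~ 3.7)
        t = np.linspace(0, 2 * np.pi, 2001)
        loop = 3.615 * np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
        g = g_vector(loop, rho=1.0)
        assert np.linalg.norm(g) == pytest.approx(2 * np.pi * 3.615**2, rel=1e-5)
        assert np.linalg.norm(g) == pytest.approx(82.1, abs=0.1)

    def test_g_zero_density_and_equivariance(self):
        t = np.linspace(0, 2 * np.pi, 100)
        loop = np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
        assert np.allclose(g_vector(loop, rho=0.0), 0.0)
        ang = 0.7
        rot = np.array(
            [[1, 0, 0], [0, np.cos(ang), -np.sin(ang)], [0, np.sin(ang), np.cos(ang)]]
        )
        g1 = g_vector(loop @ rot.T, rho=1.0)
        assert np.allclose(g1, rot @ g_vector(loop, rho=1.0), atol=1e-12)

    def test_radius_of_curvature(self):
        assert radius_of_curvature(np.array([0, 0, 9 * np.pi])) == pytest.approx(3.0)
        assert radius_of_curvature(np.array([4.0, 0, 0])) == pytest.approx(
            np.sqrt(4 / np.pi)
        )
        with pytest.raises(ValueError):
            radius_of_curvature(np.zeros(3))


class TestCoefficients:
    def test_single_tube_inertia(self):
        pm = part_morphometry("t", 0.05 * 15.0, 2 * np.sqrt(np.pi * 0.05) * 15.0, 15.0)
        assert inertia_coefficient([pm], rho=1.0) == pytest.approx(300.0)

    def test_two_parts_additivity(self):
        pm1 = part_morphometry("a", 0.05 * 5.0, 2 * np.sqrt(np.pi * 0.05) * 5.0, 5.0)
        pm2 = part_morphometry("b", 0.05 * 10.0, 2 * np.sqrt(np.pi * 0.05) * 10.0, 10.0)
        assert inertia_coefficient([pm1, pm1], 1.0) == pytest.approx(
            inertia_coefficient([pm2], 1.0)
        )

    def test_poiseuille_damping_closed_form(self):
        L, r, mu = 10.0, 0.1, 8.5e-4
        a = np.pi * r**2
        pm = part_morphometry("t", a * L, 2 * np.pi * r * L, L)
        expected = 8 * np.pi * mu * L / a**2  # == 8 mu L / (pi r^4) = 216.45
        assert damping_coefficient([pm], mu) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(216.45, abs=0.01)

    def test_damping_quarters_when_area_halves(self):
        L = 10.0
        r1, r2 = 0.1, 0.1 / np.sqrt(2)  # halved cross-section area
        mk = lambda r: part_morphometry("t", np.pi * r**2 * L, 2 * np.pi * r * L, L)
        assert damping_coefficient([mk(r2)], 1.0) == pytest.approx(
            4 * damping_coefficient([mk(r1)], 1.0), rel=1e-9
        )

    def test_piecewise_means_match_quadrature(self):
        """Part-mean cross-sections vs fine quadrature of rho * loop ds/a(s)."""
        R, a0 = 3.0, 0.05
        area_fn = lambda s: a0 * (1.0 + 0.3 * np.sin(s / R))
        total = 2 * np.pi * R
        n_parts = 50
        edges = np.linspace(0.0, total, n_parts + 1)
        parts = []
        for s0, s1 in zip(edges[:-1], edges[1:]):
            mean_a = quad(area_fn, s0, s1)[0] / (s1 - s0)
            L = s1 - s0
            parts.append(
                part_morphometry("p", mean_a * L, 2 * np.sqrt(np.pi * mean_a) * L, L)
            )
        oracle = quad(lambda s: 1.0 / area_fn(s), 0.0, total)[0]
        assert inertia_coefficient(parts, 1.0) == pytest.approx(oracle, rel=1e-2)


class TestCircuitStreamline:
    def test_closed_loop_on_fixture(self, labyrinth_fixture):
        from semiduct.mesh_io import load_geometry

        manifest, truth = labyrinth_fixture
        geo = load_geometry(manifest)
        loop, order = circuit_streamline(geo, "posterior")
        assert np.allclose(loop[0], loop[-1])
        assert polyline_length(loop) == pytest.approx(
            truth.circuits["posterior"]["length"], rel=1e-3
        )

    def test_order_independence(self, labyrinth_fixture):
        from semiduct.mesh_io import load_geometry
        from semiduct.morphometry import DEFAULT_CIRCUITS

        manifest, _ = labyrinth_fixture
        geo = load_geometry(manifest)
        shuffled = dict(DEFAULT_CIRCUITS)
        shuffled["anterior"] = tuple(reversed(DEFAULT_CIRCUITS["anterior"]))
        l1, _ = circuit_streamline(geo, "anterior")
        l2, _ = circuit_streamline(geo, "anterior", circuits=shuffled)
        assert np.linalg.norm(circuit_vector_area(l1)) == pytest.approx(
            np.linalg.norm(circuit_vector_area(l2)), rel=1e-12
        )

    def test_missing_part_raises(self, labyrinth_fixture):
        from semiduct.mesh_io import load_geometry

        manifest, _ = labyrinth_fixture
        geo = load_geometry(manifest)
        del geo.parts["amp_ant"]
        with pytest.raises(ConnectivityError):
            circuit_streamline(geo, "anterior")


class TestAreaVariationToOffset:
    def test_zero_change(self):
        assert area_variation_to_offset(0.0, 2.0, 1.0) == 0.0

    def test_circle_dilation(self):
        # (10.1)^2 / 10^2 - 1 = 0.0201
        d = area_variation_to_offset(0.0201, 10.0, 10.0)
        assert d == pytest.approx(0.1, abs=1e-6)

    def test_contraction_forward_substitution(self):
        a_ax, b_ax, change = 2.0, 1.0, -0.10
        d = area_variation_to_offset(change, a_ax, b_ax)
        assert d < 0
        assert (a_ax + d) * (b_ax + d) == pytest.approx(
            a_ax * b_ax * (1 + change), rel=1e-12
        )

    def test_collapse_raises(self):
        with pytest.raises(ValueError):
            area_variation_to_offset(-1.01, 1.0, 1.0)
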