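"""Torsion-pendulum assembly, eigen time constants, Bode, sensitivity."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from semiduct.biomech import (
    DEG,
    TorsionPendulumModel,
    analyze,
    frequency_response,
    maximal_response_axis,
    geometric_axis_angle,
    sensitivities,
    time_constants,
    velocity_sensitivity,
)
from semiduct.tables import model_from_table, primate_coefficients_path

HUMAN = dict(
    m=np.array([155.7, 176.6, 181.1]),
    c=np.array([31.2, 32.9, 45.1]),
    k=np.array([11.1, 12.6, 11.5]),
    g=np.array([92.7, 101.3, 82.1]),
    eps=np.array([268.4, 293.0, 264.6]),
    m_cc=6.9,
    m_uc=2.6,
    c_cc=0.3,
    c_uc=0.1,
)


def human_model() -> TorsionPendulumModel:
    return TorsionPendulumModel.from_coefficients(**HUMAN)


def uncoupled(m, c, k, g=(1.0, 1.0, 1.0), eps=(1.0, 1.0, 1.0)):
    return TorsionPendulumModel.from_coefficients(
        np.asarray(m, float), np.asarray(c, float), np.asarray(k, float),
        np.asarray(g, float), np.asarray(eps, float), table_units=False,
    )


class TestAssembly:
    def test_human_table_model_is_spd(self):
        model = human_model()
        assert np.all(np.linalg.eigvalsh(model.M) > 0)
        assert np.all(np.linalg.eigvalsh(model.C) > 0)
        # coupling pattern: (a,p) via cc, (a,l) via uc, (p,l) zero
        assert model.M[1, 2] == 0.0
        assert model.M[0, 1] == pytest.approx(6.9e-3)
        assert model.C[0, 2] == pytest.approx(0.1)

    def test_mg_to_g_applied_once(self):
        """tau2 must land in milliseconds, not seconds (unit harmonization)."""
        model = human_model()
        _, tau2 = time_constants(model)
        assert 3e-3 < tau2["lateral"] < 5e-3

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            TorsionPendulumModel(
                M=np.array([[1.0, 0.1, 0], [0.0, 1, 0], [0, 0, 1]]),
                C=np.eye(3), K=np.eye(3), G=np.eye(3), eps=np.ones(3),
            )

    def test_non_spd_rejected(self):
        bad = np.array([[1.0, 2.0, 0], [2.0, 1.0, 0], [0, 0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            TorsionPendulumModel(M=bad, C=np.eye(3), K=np.eye(3), G=np.eye(3), eps=np.ones(3))

    def test_shared_segment_energy(self):
        """q' M q' equals the sum of per-segment rho/a * (combined flow)^2
        on a hand-expanded two-duct toy sharing one segment."""
        # exclusive segments: L/a = 100 and 120; shared segment: L/a = 10
        m_excl = np.array([100.0, 120.0, 50.0])
        m_cc = 10.0
        model = uncoupled(m_excl + np.array([m_cc, m_cc, 0.0]), [1, 1, 1], [1, 1, 1])
        mm = model.M.copy()
        mm[0, 1] = mm[1, 0] = m_cc
        qdot = np.array([0.7, -0.3, 0.2])
        energy = qdot @ mm @ qdot
        by_hand = (
            m_excl[0] * qdot[0] ** 2
            + m_excl[1] * qdot[1] ** 2
            + m_excl[2] * qdot[2] ** 2
            + m_cc * (qdot[0] + qdot[1]) ** 2
        )
        assert energy == pytest.approx(by_hand, rel=1e-12)


class TestTimeConstants:
    def test_single_duct_quadratic_roots(self):
        """Uncoupled duct: eigen constants equal the quadratic-formula
        roots of m s^2 + c s + k = 0 (human-lateral-like numbers)."""
        m, c, k = 0.1811, 45.1, 11.5
        roots = np.roots([m, c, k])
        tau_slow, tau_fast = sorted(-1.0 / roots, reverse=True)
        model = uncoupled([m, m, m], [c, c, c], [k, k, k])
        tau1, tau2 = time_constants(model)
        assert tau1["lateral"] == pytest.approx(tau_slow, rel=1e-10)
        assert tau2["lateral"] == pytest.approx(tau_fast, rel=1e-10)
        # heavy-damping magnitudes: tau1 ~ c/k = 3.92 s, tau2 ~ m/c = 4.02 ms
        assert tau_slow == pytest.approx(3.92, abs=0.01)
        assert tau_fast == pytest.approx(4.02e-3, abs=0.01e-3)

    def test_decoupling_limit(self):
        model = uncoupled([0.2, 0.25, 0.3], [40.0, 50.0, 60.0], [10.0, 12.0, 14.0])
        tau1, tau2 = time_constants(model)
        for i, duct in enumerate(model.ducts):
            roots = np.roots([model.M[i, i], model.C[i, i], model.K[i, i]])
            ts, tf = sorted(-1.0 / roots, reverse=True)
            assert tau1[duct] == pytest.approx(ts, rel=1e-12)
            assert tau2[duct] == pytest.approx(tf, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_ode_biexponential_oracle(self, seed):
        """Eigen constants vs bi-exponential fits of brute-force ODE decays."""
        rng = np.random.default_rng(seed)
        m = 10 ** rng.uniform(-1.0, -0.5)
        c = 10 ** rng.uniform(1.4, 1.8)
        k = 10 ** rng.uniform(0.9, 1.3)
        model = uncoupled([m, m, m], [c, c, c], [k, k, k])
        tau1, tau2 = time_constants(model)
        t1, t2 = tau1["anterior"], tau2["anterior"]

        def rhs(t, y):
            return [y[1], -(c * y[1] + k * y[0]) / m]

        t_end = 5.0 * t1
        sol = solve_ivp(
            rhs, (0.0, t_end), [1.0, 0.0], method="LSODA",
            rtol=1e-10, atol=1e-12, dense_output=True,
        )
        ts = np.concatenate(
            [np.linspace(0, 20 * t2, 200), np.linspace(20 * t2, t_end, 200)]
        )
        q = sol.sol(ts)[0]

        def biexp(t, a, b, ta, tb):
            # clip exponents so stray negative taus during fitting don't overflow
            return a * np.exp(np.clip(-t / ta, -700, 50)) + b * np.exp(
                np.clip(-t / tb, -700, 50)
            )

        # crude inits from the trajectory itself (tail slope + early residual)
        tail = ts > 0.5 * t_end
        slope = np.polyfit(ts[tail], np.log(np.abs(q[tail])), 1)[0]
        p0 = [1.0, -0.01, -1.0 / slope, -1.0 / slope / 500.0]
        popt, _ = curve_fit(biexp, ts, q, p0=p0, maxfev=20000)
        fit_slow, fit_fast = sorted(popt[2:], reverse=True)
        assert fit_slow == pytest.approx(t1, rel=1e-2)
        assert fit_fast == pytest.approx(t2, rel=1e-2)

    def test_coupled_modes_reconstruct_trajectory(self):
        """The full coupled 6x6 eigendecomposition must reproduce a
        brute-force ODE trajectory of the coupled system."""
        model = human_model()
        a = model.state_matrix
        y0 = np.array([1.0, -0.5, 0.25, 0.0, 0.0, 0.0])

        def rhs(t, y):
            return a @ y

        t_eval = np.linspace(0.0, 5.0, 40)
        num = solve_ivp(rhs, (0, 5.0), y0, method="LSODA", rtol=1e-10, atol=1e-13, t_eval=t_eval)
        lam, vec = np.linalg.eig(a)
        coef = np.linalg.solve(vec, y0.astype(complex))
        modal = (vec @ (coef[:, None] * np.exp(np.outer(lam, t_eval)))).real
        assert np.allclose(num.y[:3], modal[:3], atol=1e-7)


class TestFrequencyResponse:
    def test_mid_band_plateau_and_phase(self):
        m, c, k = 0.18, 45.0, 11.5
        g, eps = 82.1, 264.6
        model = uncoupled([m] * 3, [c] * 3, [k] * 3, [g * 1e-3] * 3, [eps * 1e3] * 3)
        tau1, tau2 = time_constants(model)
        f_star = 1.0 / (2 * np.pi * np.sqrt(tau1["anterior"] * tau2["anterior"]))
        resp = frequency_response(model, np.array([1.0, 0, 0]), np.array([f_star]))
        plateau = eps * 1e3 * g * 1e-3 / c * DEG
        assert resp["gain_anterior"][0] == pytest.approx(plateau, rel=1e-6)
        assert abs(resp["phase_anterior"][0]) < 1.0  # in phase with velocity

    def test_low_frequency_asymptote(self):
        model = human_model()
        f = np.array([1e-4, 2e-4])
        resp = frequency_response(model, np.array([0, 0, 1.0]), f)
        slope = np.log10(resp["gain_lateral"][1] / resp["gain_lateral"][0]) / np.log10(2)
        assert slope == pytest.approx(1.0, abs=1e-3)  # +20 dB/decade
        assert resp["phase_lateral"][0] == pytest.approx(90.0, abs=0.5)

    def test_orthogonal_axis_silent_duct(self):
        model = uncoupled([0.2] * 3, [40.0] * 3, [10.0] * 3)
        resp = frequency_response(model, np.array([0.0, 1.0, 0.0]), np.array([1.0]))
        assert resp["gain_anterior"][0] == 0.0
        assert resp["gain_posterior"][0] > 0.0

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            frequency_response(human_model(), np.array([1.0, 0, 0]), np.array([0.0]))


class TestSensitivity:
    def test_no_coupling_axis_equals_g_direction(self):
        model = uncoupled([0.2] * 3, [40.0] * 3, [10.0] * 3)
        assert np.allclose(maximal_response_axis(model, "anterior"), [1, 0, 0])

    def test_human_coupling_tilts_axis_below_one_degree(self):
        model = human_model()
        for duct in model.ducts:
            assert geometric_axis_angle(model, duct) < 1.0

    def test_plateau_formula(self):
        model = human_model()
        s = velocity_sensitivity(model, "lateral")
        closed = model.eps[2] * np.linalg.norm(np.linalg.solve(model.C, model.G)[2]) * DEG
        assert s == pytest.approx(closed, rel=1e-2)

    def test_zero_eps_zero_sensitivity(self):
        model = uncoupled([0.2] * 3, [40.0] * 3, [10.0] * 3, eps=(0.0, 1.0, 1.0))
        assert velocity_sensitivity(model, "anterior") == 0.0

    def test_relative_sensitivities_sum_to_100(self):
        _, rel = sensitivities(human_model())
        assert sum(rel.values()) == pytest.approx(100.0)

    def test_analyze_bundles_everything(self):
        res = analyze(human_model())
        assert set(res.tau1) == {"anterior", "posterior", "lateral"}
        assert res.tau1["lateral"] > res.tau2["lateral"]


def test_bundled_primate_table_loads():
    model = model_from_table(primate_coefficients_path(), "Homo sapiens")
    assert model.M[0, 0] == pytest.approx(0.1557)
    with pytest.raises(ValueError, match="pick one"):
        model_from_table(primate_coefficients_path())
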