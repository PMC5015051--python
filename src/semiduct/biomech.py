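"""Coupled torsion-pendulum dynamics of the three semicircular ducts.

The endolymph volume displacements q = (q_a, q_p, q_l) obey

    M q'' + C q' + K q = f(t),      f_k = -(g_k . alpha''),

where M (inertia) and C (viscous damping) are symmetric 3x3 matrices
whose off-diagonal terms come from the duct segments shared between two
circuits (the common crus couples anterior/posterior, the anterior
utricle couples anterior/lateral; posterior and lateral share nothing),
K is the diagonal cupula-stiffness matrix, g_k the circuit forcing
vectors and alpha'' the head angular acceleration.

Rewriting as the first-order system x' = A x with
``A = [[0, I], [-M^-1 K, -M^-1 C]]`` gives six eigenvalues; the
reciprocal opposites of their real parts are the six time constants.
Each duct carries one long constant tau1 (slow cupula return, seconds)
and one short constant tau2 (fast fluid-inertia relaxation,
milliseconds), assigned by the dominant displacement component of the
corresponding eigenvector.

Mechanical sensitivity in the velocity bandwidth ("velocity gain") is
the mid-band cilia deflection per unit head angular velocity,
``s_k = eps_k [C^-1 G u]_k * (pi/180)`` in mdeg per deg/s about the
duct's maximal response axis u; the frequency response is exact, via
``Q(w) = (-w^2 M + i w C + K)^-1 (-w^2) G u``.

Internal units are mm-g-s; the table-facing constructor converts from
the conventional reporting units (M in mg.mm^-4, g in mg.mm^-1, eps in
mdeg per nL).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .constants import DUCTS, MG_TO_G, PER_NL_TO_PER_MM3

DEG = np.pi / 180.0


class StabilityError(ValueError):
    """Raised when the assembled system is not strictly stable."""


@dataclass
class TorsionPendulumModel:
    """Assembled torsion-pendulum system in internal (mm-g-s) units.

    ``M`` in g.mm^-4, ``C`` in g.s^-1.mm^-4, ``K`` diagonal in
    g.s^-2.mm^-4, ``G`` with rows g_k in g.mm^-1, ``eps`` in
    mdeg.mm^-3.  Duct order is (anterior, posterior, lateral).
    """

    M: np.ndarray
    C: np.ndarray
    K: np.ndarray
    G: np.ndarray
    eps: np.ndarray
    ducts: tuple[str, ...] = DUCTS

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        for name, mat in (("M", self.M), ("C", self.C)):
            if mat.shape != (3, 3):
                raise ValueError(f"{name} must be 3x3")
            if not np.allclose(mat, mat.T, rtol=1e-10, atol=0):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.linalg.eigvalsh(mat) <= 0):
                raise ValueError(f"{name} must be positive definite")
        if self.K.shape != (3, 3) or not np.allclose(self.K, np.diag(np.diag(self.K))):
            raise ValueError("K must be a diagonal 3x3 matrix")
        if np.any(np.diag(self.K) <= 0):
            raise ValueError("K must have positive diagonal")

    @classmethod
    def from_coefficients(
        cls,
        m: np.ndarray,
        c: np.ndarray,
        k: np.ndarray,
        g: np.ndarray,
        eps: np.ndarray,
        m_cc: float = 0.0,
        m_uc: float = 0.0,
        c_cc: float = 0.0,
        c_uc: float = 0.0,
        g_directions: np.ndarray | None = None,
        table_units: bool = True,
    ) -> "TorsionPendulumModel":
        """Build the model from per-duct coefficients plus couplings.

        ``m``, ``c``, ``k`` are the full per-circuit coefficients in
        duct order (anterior, posterior, lateral); ``m_cc``/``c_cc``
        couple anterior-posterior through the common crus and
        ``m_uc``/``c_uc`` anterior-lateral through the anterior utricle.
        ``g`` may be three magnitudes (3,) -- in which case the duct
        axes are taken mutually orthogonal (``g_directions`` overrides)
        -- or full 3-vectors (3, 3).  With ``table_units`` (default) the
        inputs are in reporting units: m, m_cc, m_uc and g in mg-based
        units, eps in mdeg per nL.
        """
        m = np.asarray(m, dtype=float)
        c = np.asarray(c, dtype=float)
        k = np.asarray(k, dtype=float)
        g = np.asarray(g, dtype=float)
        eps = np.asarray(eps, dtype=float)
        fm = MG_TO_G if table_units else 1.0
        fe = PER_NL_TO_PER_MM3 if table_units else 1.0
        mm = np.diag(m * fm)
        mm[0, 1] = mm[1, 0] = m_cc * fm
        mm[0, 2] = mm[2, 0] = m_uc * fm
        cm = np.diag(c)
        cm[0, 1] = cm[1, 0] = c_cc
        cm[0, 2] = cm[2, 0] = c_uc
        if g.ndim == 1:
            dirs = np.eye(3) if g_directions is None else np.asarray(g_directions, float)
            dirs = dirs / np.linalg.norm(dirs, axis=1)[:, None]
            gmat = dirs * (g * fm)[:, None]
        else:
            gmat = g * fm
        return cls(M=mm, C=cm, K=np.diag(k), G=gmat, eps=eps * fe)

    @property
    def state_matrix(self) -> np.ndarray:
        """The 6x6 first-order matrix ``[[0, I], [-M^-1 K, -M^-1 C]]``."""
        minv = np.linalg.inv(self.M)
        a = np.zeros((6, 6))
        a[:3, 3:] = np.eye(3)
        a[3:, :3] = -minv @ self.K
        a[3:, 3:] = -minv @ self.C
        return a


@dataclass
class BiomechResult:
    """Per-duct biomechanical summary."""

    tau1: dict[str, float]                 # s
    tau2: dict[str, float]                 # s (report as ms at the boundary)
    max_axis: dict[str, np.ndarray]        # unit 3-vectors
    sensitivity: dict[str, float]          # mdeg per deg/s
    relative_sensitivity: dict[str, float] = field(default_factory=dict)  # percent


def assemble_torsion_pendulum(
    circuit_coeffs: dict[str, dict[str, float]],
    shared_coeffs: dict[str, dict[str, float]],
    G: np.ndarray,
    eps: np.ndarray,
    table_units: bool = True,
) -> TorsionPendulumModel:
    """Assemble from morphometry-style coefficient dictionaries.

    ``circuit_coeffs[duct]`` holds the full-circuit ``m``, ``c``, ``k``;
    ``shared_coeffs`` holds ``{"cc": {"m", "c"}, "uc": {...}}``.
    """
    m = np.array([circuit_coeffs[d]["m"] for d in DUCTS])
    c = np.array([circuit_coeffs[d]["c"] for d in DUCTS])
    k = np.array([circuit_coeffs[d]["k"] for d in DUCTS])
    return TorsionPendulumModel.from_coefficients(
        m,
        c,
        k,
        np.asarray(G, dtype=float),
        np.asarray(eps, dtype=float),
        m_cc=shared_coeffs["cc"]["m"],
        m_uc=shared_coeffs["uc"]["m"],
        c_cc=shared_coeffs["cc"]["c"],
        c_uc=shared_coeffs["uc"]["c"],
        table_units=table_units,
    )


def time_constants(
    model: TorsionPendulumModel,
) -> tuple[dict[str, float], dict[str, float]]:
    """Six time constants of the state matrix, assigned to ducts.

    Returns ``(tau1, tau2)`` in seconds: the three slow and three fast
    constants, each mapped to its duct by the eigenvector whose
    displacement components it dominates (optimal one-to-one matching of
    modes to ducts by component magnitude).
    """
    lam, vec = np.linalg.eig(model.state_matrix)
    if np.any(lam.real >= 0):
        raise StabilityError(
            "state matrix has a non-negative eigenvalue; check the input "
            "coefficients (all must be positive, M and C positive definite)"
        )
    tau = -1.0 / lam.real
    order = np.argsort(tau)[::-1]
    slow, fast = order[:3], order[3:]

    def assign(idx: np.ndarray) -> dict[str, float]:
        # weight[i, j] = |displacement component j| of mode i
        weight = np.abs(vec[:3, idx]).T
        rows, cols = linear_sum_assignment(-weight)
        out = {}
        for r, duct_i in zip(rows, cols):
            out[model.ducts[duct_i]] = float(tau[idx[r]])
        return out

    return assign(slow), assign(fast)


def frequency_response(
    model: TorsionPendulumModel,
    axis: np.ndarray,
    freqs_hz: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Bode curves for sinusoidal rotation about a fixed axis.

    For head rotation ``alpha(t) = alpha0 exp(i w t)`` about unit axis
    ``u``, the endolymph response is
    ``Q(w) = (-w^2 M + i w C + K)^-1 (-w^2 alpha0) G u`` and the duct
    gain is ``eps_k |Q_k| / (w alpha0)`` per unit head velocity,
    reported in mdeg per deg/s; phase is relative to head angular
    velocity, in degrees.

    Returns a dict with ``freq_hz`` and per-duct ``gain_<duct>`` /
    ``phase_<duct>`` arrays.
    """
    u = np.asarray(axis, dtype=float)
    if not np.isclose(np.linalg.norm(u), 1.0, rtol=1e-6):
        raise ValueError("stimulus axis must be a unit vector")
    if freqs_hz is None:
        freqs_hz = default_frequency_grid()
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if np.any(freqs_hz <= 0):
        raise ValueError("frequency grid must be strictly positive")
    gu = model.G @ u
    gains = np.empty((len(freqs_hz), 3))
    phases = np.empty((len(freqs_hz), 3))
    for i, f in enumerate(freqs_hz):
        w = 2.0 * np.pi * f
        h = np.linalg.solve(-w * w * model.M + 1j * w * model.C + model.K, -w * w * gu)
        resp = model.eps * h              # mdeg per rad of alpha0
        vel = 1j * w                      # head velocity phasor per rad
        ratio = resp / vel                # mdeg per rad/s
        gains[i] = np.abs(ratio) * DEG    # mdeg per deg/s
        phases[i] = np.degrees(np.angle(ratio))
    out: dict[str, np.ndarray] = {"freq_hz": freqs_hz}
    for j, duct in enumerate(model.ducts):
        out[f"gain_{duct}"] = gains[:, j]
        out[f"phase_{duct}"] = phases[:, j]
    return out


def default_frequency_grid(
    f_min: float = 0.01, f_max: float = 100.0, per_decade: int = 60
) -> np.ndarray:
    """Logarithmic frequency grid (Hz) covering the trusted bandwidth."""
    n = int(np.log10(f_max / f_min) * per_decade) + 1
    return np.logspace(np.log10(f_min), np.log10(f_max), n)


def maximal_response_axis(model: TorsionPendulumModel, duct: str) -> np.ndarray:
    """Rotation axis maximising the duct's mid-band velocity gain.

    The mid-band gain about axis u is proportional to ``[C^-1 G u]_k``,
    maximised by the normalised k-th row of ``C^-1 G``.  With no
    coupling this is exactly the direction of g_k (the normal of the
    streamline plane); couplings tilt it by well under a degree in
    practice.
    """
    k = model.ducts.index(duct)
    row = np.linalg.solve(model.C, model.G)[k]
    n = np.linalg.norm(row)
    if n == 0:
        raise ValueError(f"duct {duct!r} has zero forcing")
    return row / n


def geometric_axis_angle(model: TorsionPendulumModel, duct: str) -> float:
    """Angle (deg) between the maximal response axis and g_k's direction."""
    k = model.ducts.index(duct)
    g = model.G[k] / np.linalg.norm(model.G[k])
    u = maximal_response_axis(model, duct)
    return float(np.degrees(np.arccos(np.clip(abs(g @ u), -1.0, 1.0))))


def velocity_sensitivity(model: TorsionPendulumModel, duct: str) -> float:
    """Mechanical sensitivity in the velocity bandwidth, mdeg per deg/s.

    Evaluated as the exact gain at ``w* = 1/sqrt(tau1 tau2)`` (where the
    inertial and stiffness reactances cancel) about the duct's maximal
    response axis; equals the plateau value
    ``eps_k [C^-1 G u]_k (pi/180)`` whenever tau1 >> tau2.
    """
    tau1, tau2 = time_constants(model)
    t1, t2 = tau1[duct], tau2[duct]
    if t1 <= 10.0 * t2:
        warnings.warn(
            f"duct {duct!r}: tau1/tau2 = {t1 / t2:.1f} < 10; no clean velocity "
            "bandwidth exists, sensitivity is frequency-dependent",
            stacklevel=2,
        )
    u = maximal_response_axis(model, duct)
    f_star = 1.0 / (2.0 * np.pi * np.sqrt(t1 * t2))
    resp = frequency_response(model, u, np.array([f_star]))
    return float(resp[f"gain_{duct}"][0])


def sensitivities(model: TorsionPendulumModel) -> tuple[dict[str, float], dict[str, float]]:
    """Absolute (mdeg per deg/s) and relative (%) sensitivities per duct."""
    s = {d: velocity_sensitivity(model, d) for d in model.ducts}
    total = sum(s.values())
    rel = {d: 100.0 * v / total for d, v in s.items()}
    return s, rel


def calibrate_shear_modulus(
    model: TorsionPendulumModel,
    target_avg_tau1: float,
    gamma0: float = 1.44,
    bracket: tuple[float, float] = (0.2, 10.0),
) -> float:
    """Shear modulus that makes the average long time constant hit a target.

    The cupula stiffness is exactly proportional to the shear modulus at
    fixed geometry and Poisson ratio, so scaling gamma scales K; the
    returned gamma solves ``mean(tau1) == target_avg_tau1`` given that
    ``model`` was assembled with ``gamma0``.  This is how the default
    shear modulus is anchored to a neurophysiologically measured long
    time constant.
    """
    from scipy.optimize import brentq

    def avg_tau1(gamma: float) -> float:
        scaled = TorsionPendulumModel(
            M=model.M, C=model.C, K=model.K * (gamma / gamma0),
            G=model.G, eps=model.eps, ducts=model.ducts,
        )
        tau1, _ = time_constants(scaled)
        return float(np.mean(list(tau1.values())))

    return float(
        brentq(lambda g: avg_tau1(g) - target_avg_tau1, *bracket, xtol=1e-6)
    )


def analyze(model: TorsionPendulumModel) -> BiomechResult:
    """Full biomechanical summary of an assembled model."""
    tau1, tau2 = time_constants(model)
    s, rel = sensitivities(model)
    axes = {d: maximal_response_axis(model, d) for d in model.ducts}
    return BiomechResult(
        tau1=tau1, tau2=tau2, max_axis=axes, sensitivity=s, relative_sensitivity=rel
    )
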