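"""Physiological constants and unit conventions.

Internal unit system is mm-g-s throughout the package, under which
1 Pa == 1 g.mm^-1.s^-2, so viscosities in Pa.s and moduli in Pa can be
used without conversion.  Densities are held in mg.mm^-3 at the user
boundary (the conventional reporting unit for endolymph, where water is
1.0) and converted to g.mm^-3 internally; the inertia matrix M is
likewise reported in mg.mm^-4 but assembled in g.mm^-4.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

#: Conversion from the reporting unit of the inertia coefficients
#: (mg.mm^-4) to the internal unit (g.mm^-4).
MG_TO_G = 1e-3

#: Conversion of the cilia transfer factor from mdeg.nL^-1 (reporting
#: unit; 1 nL = 1e-3 mm^3) to mdeg.mm^-3 (internal unit).
PER_NL_TO_PER_MM3 = 1e3

#: Cilia-length options (upward reach above the crista base), in mm.
CILIA_LENGTHS_MM = (0.030, 0.060, 0.090)

DUCTS = ("anterior", "posterior", "lateral")


@dataclass(frozen=True)
class PhysiologyConstants:
    """Physiological parameters of the endolymph and cupula.

    Parameters
    ----------
    rho : float
        Endolymph density in mg.mm^-3.  Default 1.0 (endolymph is
        essentially water).
    mu : float
        Endolymph dynamic viscosity in Pa.s.  Default 8.5e-4, a dilute
        aqueous value at body temperature.
    gamma : float
        Cupula shear modulus in Pa.  Default 1.44, the value obtained by
        calibrating the squirrel-monkey long time constant against its
        neurophysiologically measured 5.73 s.
    nu : float
        Cupula Poisson ratio (dimensionless).  Default 0.48: the cupula
        is a nearly incompressible hydrated gel.
    cilia_length_mm : float
        Upward reach of the stereocilia/kinocilia above the crista base,
        in mm.  One of 0.030, 0.060, 0.090 (these bracket the known
        variation of cilia length on vertebrate cristae).
    """

    rho: float = 1.0
    mu: float = 8.5e-4
    gamma: float = 1.44
    nu: float = 0.48
    cilia_length_mm: float = 0.060

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0 or self.gamma <= 0:
            raise ValueError("rho, mu and gamma must all be positive")
        if not 0 <= self.nu < 0.5:
            raise ValueError(f"Poisson ratio must lie in [0, 0.5), got {self.nu}")
        if self.cilia_length_mm <= 0:
            raise ValueError("cilia length must be positive")

    @property
    def rho_g(self) -> float:
        """Endolymph density in internal units, g.mm^-3."""
        return self.rho * MG_TO_G

    @property
    def youngs_modulus(self) -> float:
        """Cupula Young's modulus E = 2*gamma*(1+nu), in Pa."""
        return 2.0 * self.gamma * (1.0 + self.nu)

    def with_gamma(self, gamma: float) -> "PhysiologyConstants":
        return replace(self, gamma=gamma)
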