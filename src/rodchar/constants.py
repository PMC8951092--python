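"""Physical constants, solvent context and polymer parameter records.

All internal computation is SI; lengths cross module boundaries in nm and
volumes in nm**3 only where a function signature says so explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import constants as _sc

BOLTZMANN: float = _sc.k  # J K^-1
ELEMENTARY_CHARGE: float = _sc.e  # C
AVOGADRO: float = 6.02214076e23  # mol^-1 (exact, SI 2019)
VACUUM_PERMITTIVITY: float = _sc.epsilon_0  # F m^-1

NM = 1e-9  # m per nm


@dataclass(frozen=True)
class PhysicalContext:
    """Solvent and thermodynamic conditions shared by all hydrodynamic and
    electrokinetic formulas.

    Parameters
    ----------
    temperature : float
        Absolute temperature, K.
    viscosity : float
        Solvent dynamic viscosity, Pa s.
    relative_permittivity : float
        Relative dielectric constant of the solvent (dimensionless).
    solvent_density : float
        Solvent density, kg m^-3.
    """

    temperature: float = 298.15
    viscosity: float = 0.890e-3
    relative_permittivity: float = 78.5
    solvent_density: float = 997.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if self.relative_permittivity <= 1:
            raise ValueError("relative permittivity must exceed 1")
        if self.solvent_density <= 0:
            raise ValueError("solvent density must be positive")

    @property
    def kT(self) -> float:
        """Thermal energy k_B T, J."""
        return BOLTZMANN * self.temperature

    @property
    def permittivity(self) -> float:
        """Absolute solvent permittivity eps_r * eps_0, F m^-1."""
        return self.relative_permittivity * VACUUM_PERMITTIVITY

    def constants_used(self) -> dict[str, float]:
        """Constants actually entering the computations, for report provenance."""
        return {
            "temperature_K": self.temperature,
            "viscosity_Pa_s": self.viscosity,
            "relative_permittivity": self.relative_permittivity,
            "solvent_density_kg_m3": self.solvent_density,
            "boltzmann_J_per_K": BOLTZMANN,
            "elementary_charge_C": ELEMENTARY_CHARGE,
            "avogadro_per_mol": AVOGADRO,
            "vacuum_permittivity_F_per_m": VACUUM_PERMITTIVITY,
        }


@dataclass(frozen=True)
class PolymerSpec:
    """Per-monomer constants identifying a polymer species.

    Parameters
    ----------
    name : str
        Text label.
    M1 : float
        Monomer molar mass, kg mol^-1.
    lm : float
        Monomer length of the fully extended chain, nm.
    dc : float
        Extended-chain diameter, nm.
    """

    name: str
    M1: float
    lm: float
    dc: float

    def __post_init__(self) -> None:
        if self.M1 <= 0 or self.lm <= 0 or self.dc <= 0:
            raise ValueError("M1, lm and dc must all be positive")

    @property
    def Cm(self) -> float:
        """Molar mass per unit aspect ratio, M1*dc/lm, kg mol^-1."""
        return self.M1 * self.dc / self.lm


#: Poly-L-arginine with the extended-chain geometry from all-atom modelling.
P_ARG = PolymerSpec(name="poly-L-arginine", M1=0.174, lm=0.333, dc=0.84)

#: Default aqueous NaCl context (298 K water).
WATER_298K = PhysicalContext()
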