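"""Electrokinetic analysis: Debye screening, Einstein-Stokes sizing,
Lorentz-Stokes effective charge and Henry-model zeta potential.

The effective (electrokinetic) charge of a macroion follows from its
electrophoretic mobility mu_e and its friction coefficient,

    q_e = kT mu_e / D = 3 pi eta d_H mu_e,

and is typically much smaller than the nominal ionizable charge because of
counterion condensation.  The zeta potential uses the Debye-Hueckel-Henry
model with Henry's function evaluated by Ohshima's closed-form approximation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import AVOGADRO, ELEMENTARY_CHARGE, NM, PhysicalContext

log = logging.getLogger(__name__)

#: Conversion from the instrument mobility unit um cm V^-1 s^-1 to SI m^2 V^-1 s^-1.
MOBILITY_UMCM_TO_SI = 1e-8


def debye_length(ionic_strength: float, ctx: PhysicalContext) -> float:
    """Debye screening length kappa^-1 = sqrt(eps kT / (2 e^2 NA 10^3 I)), m.

    ``ionic_strength`` in mol L^-1 (1:1 electrolyte convention).
    """
    if ionic_strength <= 0:
        raise ValueError("ionic strength must be positive")
    number_density = 1000.0 * AVOGADRO * ionic_strength  # ions m^-3 per species
    return math.sqrt(ctx.permittivity * ctx.kT / (2.0 * ELEMENTARY_CHARGE**2 * number_density))


def hydrodynamic_diameter_from_diffusion(D: float, ctx: PhysicalContext) -> float:
    """Einstein-Stokes hydrodynamic diameter d_H = kT / (3 pi eta D), m."""
    if D <= 0:
        raise ValueError("diffusion coefficient must be positive")
    return ctx.kT / (3.0 * math.pi * ctx.viscosity * D)


def electrokinetic_charge(
    mobility: float,
    ctx: PhysicalContext,
    diffusion: float | None = None,
    hydrodynamic_diameter: float | None = None,
) -> float:
    """Lorentz-Stokes effective charge q_e, C.

    Exactly one of ``diffusion`` (m^2 s^-1) or ``hydrodynamic_diameter`` (m)
    must be supplied; the two routes q_e = kT mu_e/D and q_e = 3 pi eta d_H mu_e
    coincide when d_H is the Einstein-Stokes transform of D.  The sign follows
    the mobility.
    """
    if (diffusion is None) == (hydrodynamic_diameter is None):
        raise ValueError("provide exactly one of diffusion or hydrodynamic_diameter")
    if diffusion is not None:
        if diffusion <= 0:
            raise ValueError("diffusion coefficient must be positive")
        return ctx.kT * mobility / diffusion
    if hydrodynamic_diameter <= 0:
        raise ValueError("hydrodynamic diameter must be positive")
    return 3.0 * math.pi * ctx.viscosity * hydrodynamic_diameter * mobility


def charge_number(qe: float) -> float:
    """Number of elementary charges N_c = q_e / e (dimensionless, signed)."""
    return qe / ELEMENTARY_CHARGE


def ionization_degree(Nc: float, n_monomers: float) -> float:
    """Effective ionization degree alpha* = N_c / N_monomers."""
    if n_monomers <= 0:
        raise ValueError("monomer count must be positive")
    if Nc < 0:
        raise ValueError("charge number must be non-negative")
    alpha = Nc / n_monomers
    if alpha > 1:
        warnings.warn("ionization degree exceeds 1; check inputs", stacklevel=2)
    return alpha


def henry_factor(kappa_a) -> float:
    """Henry's function f(kappa a) by Ohshima's closed-form approximation,

        f = 1 + 1/2 [1 + 2.5 / (kappa a (1 + 2 exp(-kappa a)))]^-3,

    rising monotonically from 1 (Hueckel limit) to 3/2 (Smoluchowski limit).
    """
    ka = np.asarray(kappa_a, dtype=float)
    if np.any(ka < 0):
        raise ValueError("kappa a must be non-negative")
    with np.errstate(divide="ignore"):
        f = 1.0 + 0.5 / (1.0 + 2.5 / (ka * (1.0 + 2.0 * np.exp(-ka)))) ** 3
    f = np.where(ka == 0, 1.0, f)
    return f if f.ndim else float(f)


def zeta_from_mobility(
    mobility: float,
    hydrodynamic_diameter: float,
    ionic_strength: float,
    ctx: PhysicalContext,
) -> float:
    """Debye-Hueckel-Henry zeta potential, V.

        zeta = 3 eta mu_e / (2 eps f(kappa a)),  a = d_H / 2.

    ``mobility`` in SI (m^2 V^-1 s^-1), ``hydrodynamic_diameter`` in m.
    """
    if hydrodynamic_diameter <= 0:
        raise ValueError("hydrodynamic diameter must be positive")
    kappa_a = (hydrodynamic_diameter / 2.0) / debye_length(ionic_strength, ctx)
    return 3.0 * ctx.viscosity * mobility / (2.0 * ctx.permittivity * henry_factor(kappa_a))


@dataclass(frozen=True)
class ElectrokineticRecord:
    """One ionic-strength condition with its derived electrokinetic quantities.

    SI units throughout (mobility m^2 V^-1 s^-1, lengths m, charge C);
    ``ionic_strength`` in mol L^-1.
    """

    ionic_strength: float
    mobility: float
    diffusion: float
    hydrodynamic_diameter: float
    debye_length: float
    zeta: float
    charge: float
    charge_number: float
    ionization: float
    pH: float | None = None

    def __post_init__(self) -> None:
        if self.ionic_strength <= 0:
            raise ValueError("ionic strength must be positive")
        if self.diffusion > 0 and self.hydrodynamic_diameter <= 0:
            raise ValueError("hydrodynamic diameter must be positive when diffusion is")
        if abs(self.charge_number - self.charge / ELEMENTARY_CHARGE) > 1e-12 * max(1.0, abs(self.charge_number)):
            raise ValueError("charge_number must equal charge/e")
        if not 0.0 <= self.ionization <= 1.0:
            raise ValueError("ionization degree must lie in [0, 1]")

    def as_dict(self) -> dict[str, float | None]:
        return {
            "ionic_strength_M": self.ionic_strength,
            "pH": self.pH,
            "mobility_umcm_per_Vs": self.mobility / MOBILITY_UMCM_TO_SI,
            "diffusion_m2_per_s": self.diffusion,
            "hydrodynamic_diameter_nm": self.hydrodynamic_diameter / NM,
            "debye_length_nm": self.debye_length / NM,
            "zeta_mV": self.zeta * 1e3,
            "charge_C": self.charge,
            "charge_number": self.charge_number,
            "ionization_degree": self.ionization,
        }


def analyze_condition(
    ionic_strength: float,
    mobility: float,
    diffusion: float,
    n_monomers: float,
    ctx: PhysicalContext,
    pH: float | None = None,
) -> ElectrokineticRecord:
    """Derive the full electrokinetic record for one measured condition.

    ``mobility`` in SI m^2 V^-1 s^-1, ``diffusion`` in m^2 s^-1.
    """
    dH = hydrodynamic_diameter_from_diffusion(diffusion, ctx)
    qe = electrokinetic_charge(mobility, ctx, diffusion=diffusion)
    nc = charge_number(qe)
    return ElectrokineticRecord(
        ionic_strength=ionic_strength,
        mobility=mobility,
        diffusion=diffusion,
        hydrodynamic_diameter=dH,
        debye_length=debye_length(ionic_strength, ctx),
        zeta=zeta_from_mobility(mobility, dH, ionic_strength, ctx),
        charge=qe,
        charge_number=nc,
        ionization=ionization_degree(abs(nc), n_monomers),
        pH=pH,
    )
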