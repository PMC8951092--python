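"""Solute density from the dilution method, and the cylinder-geometry chain.

Densitometry of solutions with small solute mass fraction w_p gives a linear
dependence of rho_sol/rho_sys on w_p with slope s_p; the solute density is
rho_p = rho_sol/(1 + s_p).  From rho_p and molar masses the monomer and
molecule volumes follow, and the extended-chain (cylinder) geometry connects
volume, diameter and length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .constants import AVOGADRO

log = logging.getLogger(__name__)


@dataclass
class DensitySeries:
    """A density dilution series: (mass fraction w_p, system density rho_sys).

    Mass fractions are dimensionless and < 0.05 (dilute regime); densities in
    kg m^-3.
    """

    mass_fractions: np.ndarray
    densities: np.ndarray
    solvent_density: float

    def __post_init__(self) -> None:
        self.mass_fractions = np.asarray(self.mass_fractions, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.mass_fractions.shape != self.densities.shape:
            raise ValueError("mass_fractions and densities must have equal length")
        if len(self.mass_fractions) < 3:
            raise ValueError("a density series needs at least 3 records")
        if np.any(self.mass_fractions < 0) or np.any(self.mass_fractions >= 0.05):
            raise ValueError("mass fractions must satisfy 0 <= w_p < 0.05")
        if np.any(self.densities <= 0) or self.solvent_density <= 0:
            raise ValueError("all densities must be positive")


def dilution_slope(series: DensitySeries) -> float:
    """Slope s_p of rho_sol/rho_sys vs w_p, with the intercept fixed at 1.

    The intercept is pinned by construction (rho_sys -> rho_sol as w_p -> 0),
    so the fit is through-origin on y = rho_sol/rho_sys - 1.  A free-intercept
    diagnostic fit is logged for comparison.
    """
    wp = series.mass_fractions
    y = series.solvent_density / series.densities - 1.0
    if np.ptp(wp) == 0:
        raise ValueError("all mass fractions identical; slope is undetermined")
    slope = float(np.sum(wp * y) / np.sum(wp * wp))
    if len(wp) >= 3 and np.unique(wp).size >= 3:
        free = np.polyfit(wp, y, 1)
        log.info("dilution slope %.5g (free-intercept diagnostic: slope %.5g, intercept %.3g)", slope, free[0], free[1])
    return slope


def solute_density(sp: float, rho_sol: float) -> float:
    """Solute density rho_p = rho_sol / (1 + s_p), kg m^-3."""
    if sp <= -1:
        raise ValueError("dilution slope must exceed -1")
    if rho_sol <= 0:
        raise ValueError("solvent density must be positive")
    return rho_sol / (1.0 + sp)


def monomer_volume(M1: float, rho_p: float) -> float:
    """Monomer volume nu_1 = 10^27 M1/(Av rho_p), nm^3 (M1 in kg mol^-1)."""
    if M1 <= 0 or rho_p <= 0:
        raise ValueError("M1 and rho_p must be positive")
    return 1e27 * M1 / (AVOGADRO * rho_p)


def molecule_volume(Mn: float, rho_p: float) -> float:
    """Molecule volume v_m = 10^27 Mn/(rho_p Av), nm^3 (Mn in kg mol^-1)."""
    return monomer_volume(Mn, rho_p)


def monomer_count(Mn: float, M1: float) -> tuple[int, float]:
    """Average number of monomers per molecule, Mn/M1.

    Returns the rounded integer together with the unrounded ratio.
    """
    if Mn <= 0 or M1 <= 0:
        raise ValueError("Mn and M1 must be positive")
    ratio = Mn / M1
    return round(ratio), ratio


def extended_length_cylinder(vp: float, dc: float) -> float:
    """Extended (cylinder) length Le = 4 vp / (pi dc^2), nm (vp nm^3, dc nm)."""
    if vp <= 0 or dc <= 0:
        raise ValueError("vp and dc must be positive")
    return 4.0 * vp / (math.pi * dc**2)


def extended_length_from_monomers(Nm: float, lm: float) -> float:
    """Extended length from the monomer count, Nm * lm, nm."""
    if Nm <= 0 or lm <= 0:
        raise ValueError("Nm and lm must be positive")
    return Nm * lm


def equivalent_sphere_diameter(vp: float) -> float:
    """Diameter of the sphere of volume ``vp`` (nm^3): (6 vp / pi)^(1/3), nm."""
    if vp <= 0:
        raise ValueError("vp must be positive")
    return (6.0 * vp / math.pi) ** (1.0 / 3.0)
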