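"""Intrinsic viscosity from dilute-solution dilution series.

The measured quantity is the dynamic viscosity eta_p of solutions of known
mass concentration c_b.  With the solute volume fraction Phi_V = c_b/rho_p,
the reduced specific viscosity (eta_p/eta_e - 1)/Phi_V extrapolates linearly
to the intrinsic viscosity [eta] at infinite dilution (Huggins construction):

    (eta_r - 1)/Phi_V = [eta] + k_H [eta]^2 Phi_V + ...

Note: the raw ratio eta_r/Phi_V diverges as Phi_V -> 0; the quantity that is
actually extrapolated here is the reduced *specific* viscosity above, whose
intercept is finite and equals [eta].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

log = logging.getLogger(__name__)

#: Dilution series are only trusted in the dilute regime eta_r < 1.2.
RELATIVE_VISCOSITY_MAX = 1.2


def volume_fraction(cb, rho_p: float):
    """Solute volume fraction Phi_V = c_b / rho_p (both in kg m^-3)."""
    if rho_p <= 0:
        raise ValueError("solute density must be positive")
    cb_arr = np.asarray(cb, dtype=float)
    if np.any(cb_arr < 0):
        raise ValueError("mass concentration must be non-negative")
    out = cb_arr / rho_p
    return out if out.ndim else float(out)


@dataclass
class ViscositySeries:
    """One viscosity dilution series.

    Parameters
    ----------
    concentrations : array_like
        Mass concentrations c_b, kg m^-3, strictly increasing, >= 0.
    viscosities : array_like
        Solution dynamic viscosities eta_p, Pa s.
    solvent_viscosity : float
        Pure-electrolyte viscosity eta_e, Pa s.
    solute_density : float
        Solute density rho_p, kg m^-3 (converts c_b to volume fraction).
    ionic_strength : float, optional
        Metadata, mol L^-1.
    """

    concentrations: np.ndarray
    viscosities: np.ndarray
    solvent_viscosity: float
    solute_density: float
    ionic_strength: float | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viscosities = np.asarray(self.viscosities, dtype=float)
        if self.concentrations.shape != self.viscosities.shape:
            raise ValueError("concentrations and viscosities must have equal length")
        if len(self.concentrations) < 3:
            raise ValueError("a dilution series needs at least 3 records")
        if np.any(self.viscosities <= 0) or self.solvent_viscosity <= 0:
            raise ValueError("all viscosities must be positive")
        if np.any(np.diff(self.concentrations) <= 0) or self.concentrations[0] < 0:
            raise ValueError("concentrations must be non-negative and strictly increasing")
        if self.solute_density <= 0:
            raise ValueError("solute density must be positive")
        n_high = int(np.sum(self.relative_viscosity >= RELATIVE_VISCOSITY_MAX))
        if n_high:
            warnings.warn(
                f"{n_high} record(s) with relative viscosity >= {RELATIVE_VISCOSITY_MAX}: "
                "outside the dilute regime, excluded from fits",
                stacklevel=2,
            )

    @property
    def relative_viscosity(self) -> np.ndarray:
        return self.viscosities / self.solvent_viscosity

    @property
    def volume_fractions(self) -> np.ndarray:
        return volume_fraction(self.concentrations, self.solute_density)


class IntrinsicViscosityFit(NamedTuple):
    """Result of the reduced-viscosity extrapolation."""

    eta: float  # intercept: intrinsic viscosity, dimensionless
    huggins_slope: float  # slope = k_H [eta]^2, dimensionless
    stderr: float  # intercept standard error
    n_used: int
    n_excluded: int


def intrinsic_viscosity_fit(
    series: ViscositySeries, weights: str | None = None
) -> IntrinsicViscosityFit:
    """Extrapolate a dilution series to the intrinsic viscosity.

    Computes the reduced specific viscosity (eta_r - 1)/Phi_V per record and
    fits a least-squares line against Phi_V.  The intercept is [eta]; the
    slope is the quadratic (Huggins-type) coefficient k_H [eta]^2.  Records
    with eta_r >= 1.2 (outside the dilute regime) are excluded with a logged
    warning, as are zero-concentration records where the reduced viscosity is
    undefined.

    ``weights=None`` (default) is an unweighted fit.  With relative
    (multiplicative) viscometer noise the reduced-viscosity error scales as
    1/Phi_V, so ``weights="volume_fraction_squared"`` applies the matching
    inverse-variance weights Phi_V^2 and is strongly preferred for noisy data.
    """
    phi = series.volume_fractions
    eta_r = series.relative_viscosity
    keep = (phi > 0) & (eta_r < RELATIVE_VISCOSITY_MAX)
    n_excluded = int(np.sum(~keep))
    if n_excluded:
        log.warning("excluding %d record(s) outside the dilute regime or at zero concentration", n_excluded)
    phi, eta_r = phi[keep], eta_r[keep]
    if len(phi) < 3:
        raise ValueError("fewer than 3 usable records after exclusions")
    if np.ptp(phi) == 0:
        raise ValueError("all volume fractions identical; extrapolation is ill-conditioned")

    reduced = (eta_r - 1.0) / phi
    if weights is None:
        w = None
    elif weights == "volume_fraction_squared":
        w = phi  # polyfit takes w = 1/sigma, so this weights residuals by phi^2
    else:
        raise ValueError("weights must be None or 'volume_fraction_squared'")
    coeffs, cov = np.polyfit(phi, reduced, 1, w=w, cov="unscaled" if len(phi) == 3 else True)
    slope, intercept = coeffs
    stderr = float(np.sqrt(cov[1, 1]))
    log.info("[eta] = %.4g +/- %.2g, slope = %.4g (n=%d)", intercept, stderr, slope, len(phi))
    return IntrinsicViscosityFit(
        eta=float(intercept),
        huggins_slope=float(slope),
        stderr=stderr,
        n_used=int(len(phi)),
        n_excluded=n_excluded,
    )
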