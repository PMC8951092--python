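"""Slender-body intrinsic-viscosity model for rodlike macromolecules.

A rigid rod of length L and diameter d (aspect ratio lambda = L/d >> 1) has a
closed-form zero-shear intrinsic viscosity in the volume-fraction convention,

    [eta] = (3/15) lam^2/(ln 2lam - 0.5) + (1/15) lam^2/(ln 2lam - 1.5) + 14/15

for blunt cylinders.  The function is strictly increasing, so a measured
intrinsic viscosity inverts uniquely to an aspect ratio, from which the
molar mass, hydrodynamic diameter, diffusion coefficient, radius of gyration
and sedimentation coefficient of the molecule all follow.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

from .constants import AVOGADRO, NM, P_ARG, PhysicalContext, PolymerSpec

log = logging.getLogger(__name__)

# Coefficients of the blunt-cylinder slender-body viscosity law.
_C1V = 3.0 / 15.0
_C2V = 1.0 / 15.0
_CV = 14.0 / 15.0

#: Pole of the first logarithmic denominator: ln(2 lam) = 1.5.
LAMBDA_POLE = math.exp(1.5) / 2.0

#: Lower validity bound adopted for the rod model; below ~10 results are
#: order-of-magnitude only and a warning is emitted.
LAMBDA_MIN = 3.0
LAMBDA_MAX = 1e6

#: One-step inversion is quoted reliable for intrinsic viscosities above this.
ETA_ITERATIVE_MIN = 50.0


class SlenderBodyDomainError(ValueError):
    """The requested aspect ratio or intrinsic viscosity is outside the
    slender-body model's domain."""


def intrinsic_viscosity_of_aspect_ratio(lam):
    """Zero-shear intrinsic viscosity of a blunt cylinder of aspect ratio ``lam``.

    Parameters
    ----------
    lam : float or array_like
        Aspect ratio L/d; must exceed e^1.5/2 ~ 2.24 so both logarithmic
        denominators are positive.

    Returns
    -------
    float or ndarray
        Dimensionless intrinsic viscosity (volume-fraction convention).

    Raises
    ------
    SlenderBodyDomainError
        At or below the logarithmic pole, where the rod model is inapplicable.
    """
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= LAMBDA_POLE):
        raise SlenderBodyDomainError(
            f"aspect ratio must exceed e^1.5/2 = {LAMBDA_POLE:.4f}; "
            "the slender-body model is inapplicable below the pole"
        )
    if np.any((lam_arr > LAMBDA_POLE) & (lam_arr < LAMBDA_MIN)):
        warnings.warn(
            "aspect ratio below 3: slender-body viscosity is unreliable",
            stacklevel=2,
        )
    ln2l = np.log(2.0 * lam_arr)
    eta = _C1V * lam_arr**2 / (ln2l - 0.5) + _C2V * lam_arr**2 / (ln2l - 1.5) + _CV
    return eta if eta.ndim else float(eta)


def aspect_ratio_exact(eta: float, bracket: tuple[float, float] = (LAMBDA_MIN, LAMBDA_MAX)) -> float:
    """Invert the slender-body viscosity law by bracketed root finding.

    Monotonicity of the viscosity law on the bracket guarantees a unique root.

    Parameters
    ----------
    eta : float
        Dimensionless intrinsic viscosity.
    bracket : (float, float)
        Aspect-ratio search interval.

    Returns
    -------
    float
        Aspect ratio lam with f(lam) = eta to ~1e-12 relative.
    """
    lo, hi = bracket
    eta_lo = intrinsic_viscosity_of_aspect_ratio(lo)
    eta_hi = intrinsic_viscosity_of_aspect_ratio(hi)
    if not (eta_lo <= eta <= eta_hi):
        raise SlenderBodyDomainError(
            f"intrinsic viscosity {eta} outside the invertible range "
            f"[{eta_lo:.4g}, {eta_hi:.4g}] for aspect ratios in {bracket}"
        )
    lam = brentq(
        lambda x: intrinsic_viscosity_of_aspect_ratio(x) - eta,
        lo,
        hi,
        xtol=1e-12,
        rtol=1e-13,
        maxiter=200,
    )
    if lam < 10.0:
        log.warning("aspect ratio %.3f is below 10; rod model marginal", lam)
    return lam


def aspect_ratio_iterative(eta: float, fixed_point: bool = False, rtol: float = 1e-10) -> float:
    """Invert the viscosity law with the closed one-step iterative formula.

    The seed is lam1 = (15 [eta])^(1/2) and the single corrected step is

        lam = { 15 [eta] / [ 3/(ln 2lam1 - 0.5) + 1/(ln 2lam1 - 1.5) ] }^(1/2).

    Parameters
    ----------
    eta : float
        Dimensionless intrinsic viscosity.  Below 50 the one-step formula
        degrades and a warning is emitted (the quoted precision bound applies
        to [eta] >= 50).
    fixed_point : bool
        If True, keep re-substituting the estimate until |d lam|/lam < rtol
        instead of stopping after one step.

    Returns
    -------
    float
        Aspect ratio estimate.
    """
    if eta <= 0:
        raise SlenderBodyDomainError("intrinsic viscosity must be positive")
    if eta < ETA_ITERATIVE_MIN:
        warnings.warn(
            f"one-step inversion is only accurate for [eta] >= {ETA_ITERATIVE_MIN}; "
            "prefer aspect_ratio_exact",
            stacklevel=2,
        )

    def step(lam_prev: float) -> float:
        ln2l = math.log(2.0 * lam_prev)
        denom = 3.0 / (ln2l - 0.5) + 1.0 / (ln2l - 1.5)
        return math.sqrt(15.0 * eta / denom)

    lam = step(math.sqrt(15.0 * eta))
    if fixed_point:
        for _ in range(200):
            lam_next = step(lam)
            if abs(lam_next - lam) / lam < rtol:
                return lam_next
            lam = lam_next
        raise RuntimeError("fixed-point inversion did not converge")
    return lam


def molar_mass_from_aspect_ratio(
    lam: float,
    polymer: PolymerSpec | None = None,
    Cm: float | None = None,
) -> float:
    """Molar mass of the rod, Mm = (M1 dc / lm) lam = Cm lam, kg mol^-1.

    Either a :class:`PolymerSpec` (Cm computed as M1*dc/lm) or an explicit
    ``Cm`` in kg mol^-1 per unit aspect ratio must be supplied.
    """
    if (polymer is None) == (Cm is None):
        raise ValueError("provide exactly one of polymer or Cm")
    if Cm is None:
        Cm = polymer.Cm
    if lam < 0:
        raise ValueError("aspect ratio must be non-negative")
    return Cm * lam


def equivalent_cylinder(lam: float, vp: float) -> tuple[float, float]:
    """Cylinder diameter and length with aspect ratio ``lam`` and volume ``vp``.

    Parameters
    ----------
    lam : float
        Aspect ratio Lc/dc.
    vp : float
        Molecule volume, nm^3.

    Returns
    -------
    (dc, Lc) : tuple of float
        Cylinder diameter and length, nm, satisfying pi dc^2 Lc / 4 = vp.
    """
    if lam <= 0 or vp <= 0:
        raise ValueError("lam and vp must be positive")
    dc = (4.0 * vp / (math.pi * lam)) ** (1.0 / 3.0)
    return dc, lam * dc


def hydrodynamic_diameter_slender(lam, dc):
    """Hydrodynamic diameter of a slender rod, dH = lam dc / (ln 2lam - 0.11), nm.

    ``dc`` in nm; returns nm.  Raises at/below the logarithmic pole
    lam = e^0.11/2.
    """
    lam_arr = np.asarray(lam, dtype=float)
    pole = math.exp(0.11) / 2.0
    if np.any(lam_arr <= pole):
        raise SlenderBodyDomainError(f"aspect ratio must exceed e^0.11/2 = {pole:.4f}")
    out = lam_arr * np.asarray(dc, dtype=float) / (np.log(2.0 * lam_arr) - 0.11)
    return out if out.ndim else float(out)


def diffusion_from_diameter(dH_nm: float, ctx: PhysicalContext) -> float:
    """Einstein-Stokes diffusion coefficient, D = kT / (3 pi eta dH), m^2 s^-1.

    ``dH_nm`` is the hydrodynamic diameter in nm.
    """
    if dH_nm <= 0:
        raise ValueError("hydrodynamic diameter must be positive")
    return ctx.kT / (3.0 * math.pi * ctx.viscosity * dH_nm * NM)


def radius_of_gyration(lam: float, dc: float) -> float:
    """Thin-rod radius of gyration, Rg = Lc / sqrt(12) = dc lam / sqrt(12), nm."""
    if lam < 0 or dc <= 0:
        raise ValueError("lam must be >= 0 and dc > 0")
    return dc * lam / math.sqrt(12.0)


def sedimentation_coefficient(
    lam: float,
    dc: float,
    polymer: PolymerSpec | None = None,
    rho_p: float | None = None,
) -> float:
    """Shape-derived sedimentation coefficient Sc = dH / ds (dimensionless).

    ``ds`` is the diameter of the sphere with the same volume as the rod.
    With ``polymer`` and ``rho_p`` (solute density, kg m^-3) supplied, the
    rod volume is taken from the molar mass route vp = 10^27 Mm/(rho_p Av)
    with Mm = (M1 dc / lm) lam; otherwise from the cylinder geometry
    vp = pi dc^3 lam / 4.  The two agree whenever the monomer volume equals
    the cylinder slice pi dc^2 lm / 4.
    """
    dH = hydrodynamic_diameter_slender(lam, dc)
    if polymer is not None or rho_p is not None:
        if polymer is None or rho_p is None:
            raise ValueError("polymer and rho_p must be supplied together")
        mm = molar_mass_from_aspect_ratio(lam, polymer)
        vp = 1e27 * mm / (rho_p * AVOGADRO)
    else:
        vp = math.pi * dc**3 * lam / 4.0
    ds = (6.0 * vp / math.pi) ** (1.0 / 3.0)
    return dH / ds


@dataclass(frozen=True)
class SlenderBodyResult:
    """Derived-property bundle from one intrinsic viscosity.

    Lengths in nm, molar mass in kg mol^-1, diffusion in m^2 s^-1; the
    sedimentation coefficient and aspect ratio are dimensionless.
    """

    intrinsic_viscosity: float
    aspect_ratio: float
    cylinder_length: float
    cylinder_diameter: float
    molar_mass: float
    hydrodynamic_diameter: float
    diffusion_coefficient: float
    radius_of_gyration: float
    sedimentation_coefficient: float
    equivalent_sphere_diameter: float

    def __post_init__(self) -> None:
        if self.aspect_ratio <= 1:
            raise ValueError("aspect ratio must exceed 1 for a rod")
        for field in (
            "cylinder_length",
            "cylinder_diameter",
            "molar_mass",
            "hydrodynamic_diameter",
            "radius_of_gyration",
            "equivalent_sphere_diameter",
        ):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")
        lc = self.aspect_ratio * self.cylinder_diameter
        if abs(lc - self.cylinder_length) > 1e-9 * self.cylinder_length:
            raise ValueError("cylinder_length must equal aspect_ratio * cylinder_diameter")
        sc = self.hydrodynamic_diameter / self.equivalent_sphere_diameter
        if abs(sc - self.sedimentation_coefficient) > 1e-9 * sc:
            raise ValueError("sedimentation coefficient must equal dH/ds")

    def as_dict(self) -> dict[str, float]:
        return {
            "intrinsic_viscosity": self.intrinsic_viscosity,
            "aspect_ratio": self.aspect_ratio,
            "aspect_ratio_rounded": round(self.aspect_ratio),
            "cylinder_length_nm": self.cylinder_length,
            "cylinder_diameter_nm": self.cylinder_diameter,
            "molar_mass_kg_per_mol": self.molar_mass,
            "hydrodynamic_diameter_nm": self.hydrodynamic_diameter,
            "diffusion_coefficient_m2_per_s": self.diffusion_coefficient,
            "radius_of_gyration_nm": self.radius_of_gyration,
            "sedimentation_coefficient": self.sedimentation_coefficient,
            "equivalent_sphere_diameter_nm": self.equivalent_sphere_diameter,
        }


def characterize(
    eta: float,
    polymer: PolymerSpec = P_ARG,
    vp: float | None = None,
    ctx: PhysicalContext | None = None,
) -> SlenderBodyResult:
    """Full derived-property report from one intrinsic viscosity.

    The aspect ratio comes from the exact inversion.  When the molecule
    volume ``vp`` (nm^3) is known — e.g. from densitometry and a nominal
    molar mass — the cylinder diameter is rescaled so that the equivalent
    cylinder has exactly that volume; otherwise the extended-chain diameter
    of the polymer spec is used and the volume follows from the geometry.

    All downstream properties use the unrounded aspect ratio.
    """
    ctx = ctx or PhysicalContext()
    lam = aspect_ratio_exact(eta)
    if vp is None:
        dc = polymer.dc
        lc = lam * dc
        vp = math.pi * dc**2 * lc / 4.0
    else:
        dc, lc = equivalent_cylinder(lam, vp)
    mm = molar_mass_from_aspect_ratio(lam, Cm=polymer.M1 * dc / polymer.lm)
    dH = hydrodynamic_diameter_slender(lam, dc)
    ds = (6.0 * vp / math.pi) ** (1.0 / 3.0)
    return SlenderBodyResult(
        intrinsic_viscosity=eta,
        aspect_ratio=lam,
        cylinder_length=lc,
        cylinder_diameter=dc,
        molar_mass=mm,
        hydrodynamic_diameter=dH,
        diffusion_coefficient=diffusion_from_diameter(dH, ctx),
        radius_of_gyration=radius_of_gyration(lam, dc),
        sedimentation_coefficient=dH / ds,
        equivalent_sphere_diameter=ds,
    )


@dataclass(frozen=True)
class PowerLawFit:
    """Power-law interpolant y = offset + coefficient * [eta]^exponent."""

    offset: float
    coefficient: float
    exponent: float
    fit_range: tuple[float, float]
    rms_relative_error: float

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("coefficient must be positive")
        if self.rms_relative_error < 0:
            raise ValueError("rms_relative_error must be non-negative")

    def __call__(self, eta):
        return self.offset + self.coefficient * np.asarray(eta, dtype=float) ** self.exponent


def _loglog_fit(eta: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    b, log_c = np.polyfit(np.log(eta), np.log(y), 1)
    return math.exp(log_c), b


def fit_interpolants(
    eta_range: tuple[float, float] = (50.0, 600.0),
    n_points: int = 200,
    polymer: PolymerSpec = P_ARG,
) -> dict[str, PowerLawFit]:
    """Fit power-law interpolants to the exact inversion curve.

    Samples the exact aspect-ratio curve on a log-uniform intrinsic-viscosity
    grid and fits lam = C [eta]^b (log-log least squares); the molar mass and
    radius of gyration are the same fit scaled by Cm and dc/sqrt(12).  The
    hydrodynamic diameter and sedimentation coefficient use an offset form
    a + C [eta]^b via nonlinear least squares initialized from the log-log fit
    of the offset-subtracted curve.

    Returns
    -------
    dict
        Keys ``aspect_ratio``, ``molar_mass``, ``radius_of_gyration``,
        ``hydrodynamic_diameter``, ``sedimentation_coefficient``.
    """
    lo, hi = eta_range
    if n_points < 20:
        raise ValueError("need at least 20 grid points")
    eta = np.geomspace(lo, hi, n_points)
    lam = np.array([aspect_ratio_exact(e) for e in eta])

    def pure(y: np.ndarray) -> PowerLawFit:
        c, b = _loglog_fit(eta, y)
        pred = c * eta**b
        rms = float(np.sqrt(np.mean(((pred - y) / y) ** 2)))
        return PowerLawFit(0.0, c, b, (lo, hi), rms)

    def offset(y: np.ndarray) -> PowerLawFit:
        a0 = 0.5 * float(y.min())
        c0, b0 = _loglog_fit(eta, y - a0)
        try:
            popt, _ = curve_fit(
                lambda x, a, c, b: a + c * x**b,
                eta,
                y,
                p0=(a0, c0, b0),
                maxfev=20000,
            )
        except RuntimeError as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"offset power-law fit failed to converge: {exc}") from exc
        a, c, b = popt
        pred = a + c * eta**b
        rms = float(np.sqrt(np.mean(((pred - y) / y) ** 2)))
        return PowerLawFit(float(a), float(c), float(b), (lo, hi), rms)

    dH = hydrodynamic_diameter_slender(lam, polymer.dc)
    vp = math.pi * polymer.dc**3 * lam / 4.0
    ds = (6.0 * vp / math.pi) ** (1.0 / 3.0)
    fits = {
        "aspect_ratio": pure(lam),
        "molar_mass": pure(polymer.Cm * lam),
        "radius_of_gyration": pure(polymer.dc * lam / math.sqrt(12.0)),
        "hydrodynamic_diameter": offset(dH),
        "sedimentation_coefficient": offset(dH / ds),
    }
    for name, fit in fits.items():
        log.info("interpolant %s: a=%.4g C=%.4g b=%.4g rms=%.3g", name, fit.offset, fit.coefficient, fit.exponent, fit.rms_relative_error)
    return fits
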