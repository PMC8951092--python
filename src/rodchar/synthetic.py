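"""Seeded generators emulating each measurement stage.

Every generator is a pure function of (seed, parameters): the same
configuration reproduces the same dataset bit for bit.  Defaults mirror the
study conditions: dilution series of up to 10 points between 50 and 500
mg L^-1, density series with mass fractions up to 5e-4 and the densitometer's
5e-3 kg m^-3 absolute precision, and chain tables for 25-50 monomers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .chain_geometry import EtETable
from .constants import PhysicalContext
from .densitometry import DensitySeries
from .electrokinetics import ElectrokineticRecord, analyze_condition
from .viscometry import ViscositySeries

#: Densitometer absolute precision, kg m^-3.
DENSITY_NOISE_DEFAULT = 5e-3

#: Typical Huggins coefficient for a polyelectrolyte in added salt.
HUGGINS_DEFAULT = 0.3


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration shared by all generators.

    ``noise_level`` is a relative standard deviation for the multiplicative
    noise models (viscosity, mobility, diffusion) and an absolute standard
    deviation in kg m^-3 for the additive densitometer noise.  ``truth``
    carries the generating parameters of the specific stage.
    """

    seed: int
    n_points: int = 10
    noise_level: float = 0.0
    truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_level < 0:
            raise ValueError("noise level must be non-negative")
        if self.n_points < 3:
            raise ValueError("need at least 3 points")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_viscometry(config: GeneratorConfig) -> ViscositySeries:
    """Dilution series with relative viscosity 1 + [eta] Phi + kH ([eta] Phi)^2.

    ``truth`` keys: ``eta`` (intrinsic viscosity, required), ``kH`` (Huggins
    coefficient, default 0.3), ``solvent_viscosity`` (Pa s, default 0.89e-3),
    ``solute_density`` (kg m^-3, default 1500).  Concentrations are equally
    spaced on [50, 500] mg L^-1; noise is multiplicative Gaussian on the
    solution viscosity.
    """
    truth = config.truth
    eta_true = float(truth["eta"])
    if eta_true <= 0:
        raise ValueError("true intrinsic viscosity must be positive")
    kh = float(truth.get("kH", HUGGINS_DEFAULT))
    eta_e = float(truth.get("solvent_viscosity", 0.890e-3))
    rho_p = float(truth.get("solute_density", 1500.0))
    rng = config.rng()
    cb = np.linspace(0.05, 0.5, config.n_points)  # kg m^-3 == 50..500 mg/L
    phi = cb / rho_p
    eta_r = 1.0 + eta_true * phi + kh * (eta_true * phi) ** 2
    eta_p = eta_e * eta_r * (1.0 + config.noise_level * rng.standard_normal(config.n_points))
    return ViscositySeries(
        concentrations=cb,
        viscosities=eta_p,
        solvent_viscosity=eta_e,
        solute_density=rho_p,
        ionic_strength=truth.get("ionic_strength"),
    )


def gen_density_series(config: GeneratorConfig) -> DensitySeries:
    """Density dilution series from the exact linear law plus instrument noise.

    ``truth`` keys: ``rho_p`` (solute density, kg m^-3, required), ``rho_sol``
    (solvent density, default 997).  Mass fractions are an even grid on
    [0, 5e-4]; rho_sys follows rho_sol/rho_sys = 1 + s_p w_p with
    s_p = rho_sol/rho_p - 1, plus additive Gaussian noise of absolute level
    ``noise_level`` kg m^-3 (use DENSITY_NOISE_DEFAULT for the densitometer).
    """
    truth = config.truth
    rho_p = float(truth["rho_p"])
    rho_sol = float(truth.get("rho_sol", 997.0))
    if rho_p <= 0 or rho_sol <= 0:
        raise ValueError("densities must be positive")
    sp = rho_sol / rho_p - 1.0
    rng = config.rng()
    wp = np.linspace(0.0, 5e-4, config.n_points)
    rho_sys = rho_sol / (1.0 + sp * wp) + config.noise_level * rng.standard_normal(config.n_points)
    return DensitySeries(mass_fractions=wp, densities=rho_sys, solvent_density=rho_sol)


def _rotate_about(u: np.ndarray, cos_t: float, sin_t: float, rng: np.random.Generator) -> np.ndarray:
    """New unit vectors at fixed polar angle from ``u`` with uniform azimuth."""
    n = len(u)
    # per-row reference axis least aligned with u, for a stable orthobasis
    ref = np.eye(3)[np.argmin(np.abs(u), axis=1)]
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(u, e1)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=(n, 1))
    return cos_t * u + sin_t * (np.cos(phi) * e1 + np.sin(phi) * e2)


def _chain_ete(n_bonds: int, bond: float, stiffness: float, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Per-frame EtE of a freely rotating chain with fixed bond length.

    ``stiffness`` is the cosine of the fixed bond angle between successive
    bonds: 1 gives a straight rod with EtE = n_bonds * bond in every frame,
    0 the ideal (random-walk) limit.
    """
    if not 0.0 <= stiffness <= 1.0:
        raise ValueError("stiffness must lie in [0, 1]")
    if stiffness == 1.0:
        return np.full(n_frames, n_bonds * bond)
    u = rng.standard_normal((n_frames, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = u.copy()
    cos_t = stiffness
    sin_t = math.sqrt(1.0 - stiffness**2)
    for _ in range(n_bonds - 1):
        u = _rotate_about(u, cos_t, sin_t, rng)
        r += u
    return bond * np.linalg.norm(r, axis=1)


def gen_ete_table(config: GeneratorConfig) -> EtETable:
    """Per-frame EtE tables from a freely rotating chain model.

    ``truth`` keys: ``bond_length`` (nm, required), ``stiffness`` (cosine of
    the bond angle, default 0 = flexible; 1 = fully extended), ``n_frames``
    (default 1000), ``monomer_counts`` (default 25..50 in steps of 5),
    ``monomer_volume`` (nm^3, optional, fills the volume column as Nm * nu1).
    A chain of Nm monomers carries Nm - 1 bonds, so the fully stiff limit has
    EtE = (Nm - 1) * bond_length in every frame.
    """
    truth = config.truth
    b = float(truth["bond_length"])
    if b <= 0:
        raise ValueError("bond length must be positive")
    stiffness = float(truth.get("stiffness", 0.0))
    n_frames = int(truth.get("n_frames", 1000))
    counts: Sequence[int] = truth.get("monomer_counts", (25, 30, 35, 40, 45, 50))
    rng = config.rng()
    frames = {int(n): _chain_ete(int(n) - 1, b, stiffness, n_frames, rng) for n in counts}
    volumes = None
    if "monomer_volume" in truth:
        volumes = np.array([n * float(truth["monomer_volume"]) for n in sorted(frames)])
    return EtETable.from_frames(frames, molecule_volumes=volumes)


def gen_electrokinetic_records(config: GeneratorConfig) -> list[ElectrokineticRecord]:
    """Mobility/diffusion records consistent with a known effective charge.

    ``truth`` keys: ``qe`` (effective charge, C, required), ``dH``
    (hydrodynamic diameter, m, required), ``n_monomers`` (default 241),
    ``ionic_strengths`` (mol L^-1, default the four NaCl conditions
    1e-4..0.15), ``context`` (PhysicalContext).  The diffusion coefficient is
    the Einstein-Stokes transform of dH and the mobility the exact
    Lorentz-Stokes inverse of qe; both carry multiplicative Gaussian noise of
    the configured relative level.
    """
    truth = config.truth
    qe = float(truth["qe"])
    dh = float(truth["dH"])
    if dh <= 0:
        raise ValueError("hydrodynamic diameter must be positive")
    n_monomers = float(truth.get("n_monomers", 241))
    strengths = truth.get("ionic_strengths", (1e-4, 1e-3, 1e-2, 0.15))
    ctx: PhysicalContext = truth.get("context", PhysicalContext())
    rng = config.rng()
    d_true = ctx.kT / (3.0 * math.pi * ctx.viscosity * dh)
    mu_true = qe * d_true / ctx.kT
    records = []
    for ionic_strength in strengths:
        d = d_true * (1.0 + config.noise_level * rng.standard_normal())
        mu = mu_true * (1.0 + config.noise_level * rng.standard_normal())
        records.append(analyze_condition(float(ionic_strength), mu, d, n_monomers, ctx))
    return records
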