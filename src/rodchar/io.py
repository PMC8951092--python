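"""CSV readers/writers, JSON reports and the end-to-end characterization pipeline.

CSV conventions: comma-separated UTF-8, one header row, period decimal
separator, units encoded in column names.  Display units follow laboratory
practice (nm, kg mol^-1, um cm V^-1 s^-1, mV, mol L^-1); everything internal
is SI.  JSON reports use sorted keys and floats rounded to 6 significant
digits so identical inputs give byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from . import densitometry, viscometry
from .chain_geometry import EtETable
from .constants import AVOGADRO, P_ARG, PhysicalContext, PolymerSpec
from .electrokinetics import MOBILITY_UMCM_TO_SI, ElectrokineticRecord, analyze_condition
from .slender_body import SlenderBodyResult, characterize
from .synthetic import DENSITY_NOISE_DEFAULT, GeneratorConfig, gen_density_series, gen_electrokinetic_records, gen_ete_table, gen_viscometry
from .viscometry import ViscositySeries

log = logging.getLogger(__name__)

try:
    __version__ = metadata.version("rodchar")
except metadata.PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"

VISCOSITY_COLUMNS = ["conc_mg_per_L", "viscosity_mPa_s"]
DENSITY_COLUMNS = ["mass_fraction", "density_kg_m3"]
ELECTROKINETICS_COLUMNS = ["ionic_strength_M", "pH", "mobility_umcm_per_Vs", "diffusion_m2_per_s"]
ETE_LONG_COLUMNS = ["n_monomers", "frame", "ete_nm"]
ETE_SUMMARY_COLUMNS = ["n_monomers", "ete_avg_nm", "ete_max_nm"]


class CsvFormatError(ValueError):
    """A CSV input does not match the expected schema."""


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise CsvFormatError(f"{path}: could not parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CsvFormatError(
            f"{path}, header line 1: missing column(s) {missing}; expected columns {required}"
        )
    return df


def read_viscosity_csv(
    path: str | Path,
    solvent_viscosity_mPa_s: float,
    solute_density: float,
    ionic_strength: float | None = None,
) -> ViscositySeries:
    """Read a `conc_mg_per_L, viscosity_mPa_s` dilution series."""
    df = _read_csv(path, VISCOSITY_COLUMNS).sort_values("conc_mg_per_L")
    return ViscositySeries(
        concentrations=df["conc_mg_per_L"].to_numpy() * 1e-3,  # mg/L -> kg/m^3
        viscosities=df["viscosity_mPa_s"].to_numpy() * 1e-3,  # mPa s -> Pa s
        solvent_viscosity=solvent_viscosity_mPa_s * 1e-3,
        solute_density=solute_density,
        ionic_strength=ionic_strength,
    )


def write_viscosity_csv(series: ViscositySeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "conc_mg_per_L": series.concentrations * 1e3,
            "viscosity_mPa_s": series.viscosities * 1e3,
        }
    ).to_csv(path, index=False)


def read_density_csv(path: str | Path, solvent_density: float) -> densitometry.DensitySeries:
    """Read a `mass_fraction, density_kg_m3` dilution series."""
    df = _read_csv(path, DENSITY_COLUMNS).sort_values("mass_fraction")
    return densitometry.DensitySeries(
        mass_fractions=df["mass_fraction"].to_numpy(),
        densities=df["density_kg_m3"].to_numpy(),
        solvent_density=solvent_density,
    )


def write_density_csv(series: densitometry.DensitySeries, path: str | Path) -> None:
    pd.DataFrame(
        {"mass_fraction": series.mass_fractions, "density_kg_m3": series.densities}
    ).to_csv(path, index=False)


def read_electrokinetics_csv(path: str | Path) -> pd.DataFrame:
    """Read `ionic_strength_M, pH, mobility_umcm_per_Vs, diffusion_m2_per_s`."""
    return _read_csv(path, ELECTROKINETICS_COLUMNS)


def write_electrokinetics_csv(records: list[ElectrokineticRecord], path: str | Path) -> None:
    rows = [r.as_dict() for r in records]
    pd.DataFrame(rows)[ELECTROKINETICS_COLUMNS].to_csv(path, index=False)


def read_ete_csv(path: str | Path) -> EtETable:
    """Read an EtE table in long (`n_monomers, frame, ete_nm`) or summary
    (`n_monomers, ete_avg_nm, ete_max_nm`) format."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise CsvFormatError(f"{path}: could not parse CSV ({exc})") from exc
    if set(ETE_LONG_COLUMNS) <= set(df.columns):
        frames = {
            int(n): g["ete_nm"].to_numpy(dtype=float)
            for n, g in df.groupby("n_monomers")
        }
        return EtETable.from_frames(frames)
    if set(ETE_SUMMARY_COLUMNS) <= set(df.columns):
        df = df.sort_values("n_monomers")
        return EtETable(
            n_monomers=df["n_monomers"].to_numpy(dtype=float),
            ete_avg=df["ete_avg_nm"].to_numpy(dtype=float),
            ete_max=df["ete_max_nm"].to_numpy(dtype=float),
        )
    raise CsvFormatError(
        f"{path}, header line 1: expected columns {ETE_LONG_COLUMNS} or {ETE_SUMMARY_COLUMNS}; "
        f"found {list(df.columns)}"
    )


def read_polymer_json(path: str | Path) -> PolymerSpec:
    """Read a polymer spec: {"name", "M1_kg_per_mol", "lm_nm", "dc_nm"}."""
    data = json.loads(Path(path).read_text())
    try:
        return PolymerSpec(
            name=data["name"], M1=data["M1_kg_per_mol"], lm=data["lm_nm"], dc=data["dc_nm"]
        )
    except KeyError as exc:
        raise CsvFormatError(f"{path}: polymer spec missing key {exc}") from exc


# ---------------------------------------------------------------------------
# JSON report


def _round_floats(obj, sig: int = 6):
    """Round every float to ``sig`` significant digits for stable output."""
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        return float(f"{x:.{sig}g}") if np.isfinite(x) else x
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def to_stable_json(payload: dict) -> str:
    """Serialize with sorted keys and 6-significant-digit floats."""
    return json.dumps(_round_floats(payload), sort_keys=True, indent=2) + "\n"


def _digest(path: str | Path | None) -> str | None:
    if path is None:
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class CharacterizationReport:
    """Full per-condition characterization with provenance."""

    polymer: PolymerSpec
    context: PhysicalContext
    conditions: list[dict] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_payload(self) -> dict:
        return {
            "polymer": {
                "name": self.polymer.name,
                "M1_kg_per_mol": self.polymer.M1,
                "lm_nm": self.polymer.lm,
                "dc_nm": self.polymer.dc,
            },
            "constants": self.context.constants_used(),
            "conditions": self.conditions,
            "errors": self.errors,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return to_stable_json(self.to_payload())


def run_full_characterization(
    viscosity_csv: str | Path,
    density_csv: str | Path | None = None,
    electrokinetics_csv: str | Path | None = None,
    polymer: PolymerSpec = P_ARG,
    ctx: PhysicalContext | None = None,
    solvent_viscosity_mPa_s: float | None = None,
    molar_mass_nominal: float | None = None,
    ionic_strength: float | None = None,
) -> CharacterizationReport:
    """Run the full workflow: densitometry -> viscometry -> rod model -> electrokinetics.

    The density stage (optional) supplies the solute density rho_p; with a
    nominal molar mass it also fixes the molecule volume fed to the rod model.
    The electrokinetics stage (optional) adds per-ionic-strength charge and
    zeta columns.  Stage failures are collected as labelled error strings and
    leave the corresponding block null.
    """
    ctx = ctx or PhysicalContext()
    if solvent_viscosity_mPa_s is None:
        solvent_viscosity_mPa_s = ctx.viscosity * 1e3
    report = CharacterizationReport(polymer=polymer, context=ctx)
    report.provenance = {
        "tool_version": __version__,
        "inputs": {
            "viscosity_csv": _digest(viscosity_csv),
            "density_csv": _digest(density_csv),
            "electrokinetics_csv": _digest(electrokinetics_csv),
        },
        "molar_mass_nominal_kg_per_mol": molar_mass_nominal,
    }

    # densitometry
    rho_p = 1500.0  # default solute density when no density series is supplied
    density_block = None
    if density_csv is not None:
        try:
            dseries = read_density_csv(density_csv, ctx.solvent_density)
            sp = densitometry.dilution_slope(dseries)
            rho_p = densitometry.solute_density(sp, ctx.solvent_density)
            density_block = {"dilution_slope": sp, "solute_density_kg_m3": rho_p}
        except Exception as exc:
            report.errors.append(f"densitometry: {exc}")

    # viscometry
    eta_fit = None
    try:
        vseries = read_viscosity_csv(
            viscosity_csv, solvent_viscosity_mPa_s, rho_p, ionic_strength
        )
        eta_fit = viscometry.intrinsic_viscosity_fit(vseries)
    except Exception as exc:
        report.errors.append(f"viscometry: {exc}")

    # slender-body characterization
    rod_block = None
    vp = None
    if molar_mass_nominal is not None:
        vp = densitometry.molecule_volume(molar_mass_nominal, rho_p)
    if eta_fit is not None:
        try:
            result: SlenderBodyResult = characterize(eta_fit.eta, polymer, vp=vp, ctx=ctx)
            rod_block = result.as_dict()
        except Exception as exc:
            report.errors.append(f"slender_body: {exc}")

    # electrokinetics
    ek_block = None
    if electrokinetics_csv is not None:
        try:
            df = read_electrokinetics_csv(electrokinetics_csv)
            n_monomers = 241.0
            if molar_mass_nominal is not None:
                n_monomers = molar_mass_nominal / polymer.M1
            ek_block = []
            for row in df.itertuples(index=False):
                rec = analyze_condition(
                    ionic_strength=float(row.ionic_strength_M),
                    mobility=float(row.mobility_umcm_per_Vs) * MOBILITY_UMCM_TO_SI,
                    diffusion=float(row.diffusion_m2_per_s),
                    n_monomers=n_monomers,
                    ctx=ctx,
                    pH=float(row.pH) if np.isfinite(row.pH) else None,
                )
                ek_block.append(rec.as_dict())
        except Exception as exc:
            report.errors.append(f"electrokinetics: {exc}")
            ek_block = None

    report.conditions.append(
        {
            "ionic_strength_M": ionic_strength,
            "density": density_block,
            "intrinsic_viscosity": None
            if eta_fit is None
            else {
                "eta": eta_fit.eta,
                "huggins_slope": eta_fit.huggins_slope,
                "stderr": eta_fit.stderr,
                "n_used": eta_fit.n_used,
                "n_excluded": eta_fit.n_excluded,
            },
            "slender_body": rod_block,
            "electrokinetics": ek_block,
        }
    )
    return report


# ---------------------------------------------------------------------------
# generator dispatch used by the CLI


def generate_csv(kind: str, seed: int, out: str | Path, noise: float | None = None) -> None:
    """Generate a synthetic dataset of the given kind and write its CSV."""
    out = Path(out)
    if kind == "viscometry":
        cfg = GeneratorConfig(seed=seed, noise_level=0.01 if noise is None else noise, truth={"eta": 490.0})
        write_viscosity_csv(gen_viscometry(cfg), out)
    elif kind == "density":
        cfg = GeneratorConfig(
            seed=seed,
            noise_level=DENSITY_NOISE_DEFAULT if noise is None else noise,
            truth={"rho_p": 1500.0},
        )
        write_density_csv(gen_density_series(cfg), out)
    elif kind == "ete":
        cfg = GeneratorConfig(
            seed=seed, truth={"bond_length": 0.333, "stiffness": 0.0, "n_frames": 1000}
        )
        gen_ete_table(cfg).to_long_frame().to_csv(out, index=False)
    elif kind == "electrokinetics":
        cfg = GeneratorConfig(
            seed=seed,
            noise_level=0.05 if noise is None else noise,
            truth={"qe": 40 * 1.602176634e-19, "dH": 12e-9},
        )
        records = gen_electrokinetic_records(cfg)
        rows = [
            {
                "ionic_strength_M": r.ionic_strength,
                "pH": 5.6,
                "mobility_umcm_per_Vs": r.mobility / MOBILITY_UMCM_TO_SI,
                "diffusion_m2_per_s": r.diffusion,
            }
            for r in records
        ]
        pd.DataFrame(rows).to_csv(out, index=False)
    else:
        raise ValueError(f"unknown generator kind: {kind}")
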