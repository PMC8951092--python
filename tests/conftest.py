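import numpy as np
import pytest

from rodchar import PhysicalContext


@pytest.fixture(scope="session")
def ctx() -> PhysicalContext:
    """Aqueous NaCl at 298 K, the measurement conditions."""
    return PhysicalContext()


@pytest.fixture(scope="session")
def chain_table():
    """Published per-chain-length summaries from the all-atom runs:
    monomer counts, average and maximum end-to-end distances (nm)."""
    return {
        "n_monomers": np.array([25, 30, 35, 40, 45, 50], dtype=float),
        "ete_avg": np.array([5.95, 6.42, 8.17, 8.93, 10.24, 10.78]),
        "ete_max": np.array([8.38, 9.89, 11.48, 13.24, 15.16, 16.77]),
        "molecule_volume": np.array([4.58, 5.49, 6.41, 7.32, 8.24, 9.15]),
    }


@pytest.fixture(scope="session")
def rod_table():
    """Published intrinsic-viscosity / rod-geometry rows:
    (eta, lam +/- tol, Lc +/- tol, dc +/- tol), volume 46.5 nm^3."""
    return [
        # eta,  (lam, tol), (Lc, tol), (dc, tol)
        (490.0, (89, 3), (79, 3), (0.87, 0.02)),
        (360.0, (75, 3), (70, 3), (0.93, 0.02)),
        (180.0, (51, 3), (54, 2), (1.06, 0.03)),
        (90.0, (34, 2), (41, 2), (1.20, 0.05)),
        (62.0, (28, 2), (36, 2), (1.30, 0.05)),
    ]


@pytest.fixture(scope="session")
def mobility_table():
    """Published electrokinetic rows: ionic strength (M), Debye length (nm),
    diffusion coefficient (m^2/s), hydrodynamic diameter (nm),
    mobility (um cm / V s), zeta (mV)."""
    return [
        (1e-5, 68.7, 2.9e-11, 17, 4.7, 85),
        (1e-4, 30.5, 4.1e-11, 12, 4.2, 78),
        (1e-3, 9.63, 4.5e-11, 11, 3.7, 70),
        (1e-2, 3.05, 4.9e-11, 10, 3.2, 55),
        (0.15, 0.786, 6.1e-11, 8, 2.1, 38),
    ]
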