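"""Deterministic synthetic inputs: random aggregates and structured densities.

The generator emulates the two ingredients a real calculation is fed from
experiment: a small Hermitian one-exciton Hamiltonian (site energies plus
symmetric couplings) and a positive, multi-peaked ("structured") bath
spectral density tabulated on a frequency grid.  Identical spec + seed
produce byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .exciton_model import (
    DrudeLorentzDensity,
    ExcitonSystem,
    SpectralDensity,
    TabulatedDensity,
    build_exciton_system,
    write_exciton_file,
    write_spectral_density_table,
)

__all__ = ["LorentzianPeak", "FixtureSpec", "random_exciton_system",
           "fmo_like_system", "fixture_spectral_density", "generate_fixture",
           "scan_fixture_spec"]


@dataclass(frozen=True)
class LorentzianPeak:
    """One Lorentzian line of a structured density: height * w^2 / ((x-c)^2 + w^2)."""

    center: float   # cm^-1
    width: float    # cm^-1 (HWHM)
    height: float   # cm^-1 (peak value of J)


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for a synthetic aggregate + bath density."""

    n_sites: int = 7
    energy_spread: float = 120.0     # cm^-1, std of site energies
    coupling_scale: float = 60.0     # cm^-1, std of off-diagonal couplings
    bath_kind: str = "peaks"         # "peaks" or "drude"
    peaks: tuple[LorentzianPeak, ...] = (
        LorentzianPeak(70.0, 20.0, 20.0),
        LorentzianPeak(165.0, 30.0, 25.0),
        LorentzianPeak(240.0, 25.0, 15.0),
    )
    lambda_reorg: float = 35.0       # drude branch
    gamma: float = 100.0
    n_modes: int = 10
    omega_min: float = 30.0
    omega_max: float = 300.0
    table_points: int = 200
    seed: int = 7

    def __post_init__(self):
        if self.bath_kind not in ("peaks", "drude"):
            raise ValueError(f"unknown bath kind {self.bath_kind!r}")
        if self.n_sites < 1 or self.n_modes < 1:
            raise ValueError("n_sites and n_modes must be >= 1")


def random_exciton_system(spec: FixtureSpec) -> ExcitonSystem:
    """Random Hermitian one-exciton Hamiltonian from the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    eps = spec.energy_spread * rng.standard_normal(spec.n_sites)
    j = spec.coupling_scale * rng.standard_normal((spec.n_sites, spec.n_sites))
    j = 0.5 * (j + j.T)
    np.fill_diagonal(j, 0.0)
    return build_exciton_system(eps, j)


def fmo_like_system() -> ExcitonSystem:
    """Synthetic deterministic 7-site aggregate with FMO-like topology.

    Entirely invented numbers (no published parameter set is reproduced),
    but with the structural features that shape energy transfer in a
    7-pigment light-harvesting monomer: a strongly coupled site-1/site-2
    dimer fed by the initial excitation, a low-energy trap at site 3, and a
    second relay through sites 4-7.  Energies and couplings in cm^-1.
    """
    eps = [250.0, 280.0, 0.0, 110.0, 270.0, 420.0, 230.0]
    j = np.zeros((7, 7))
    pairs = {
        (0, 1): -90.0, (0, 2): 6.0, (0, 3): -6.0, (0, 4): 7.0, (0, 5): -14.0, (0, 6): -10.0,
        (1, 2): 30.0, (1, 3): 8.0, (1, 4): 1.0, (1, 5): 12.0, (1, 6): 5.0,
        (2, 3): -55.0, (2, 4): -1.0, (2, 5): -8.0, (2, 6): 2.0,
        (3, 4): -65.0, (3, 5): -18.0, (3, 6): -60.0,
        (4, 5): 80.0, (4, 6): -3.0,
        (5, 6): 35.0,
    }
    for (a, b), v in pairs.items():
        j[a, b] = j[b, a] = v
    return build_exciton_system(eps, j)


def _peaks_density(peaks, omega):
    omega = np.asarray(omega, dtype=float)
    out = np.zeros_like(omega)
    for p in peaks:
        out += p.height * p.width**2 / ((omega - p.center) ** 2 + p.width**2)
    return out


def fixture_spectral_density(spec: FixtureSpec) -> SpectralDensity:
    """The spec's bath density: Drude-Lorentz or a tabulated sum of peaks."""
    if spec.bath_kind == "drude":
        return DrudeLorentzDensity(lambda_reorg=spec.lambda_reorg, gamma=spec.gamma)
    grid = np.linspace(spec.omega_min, spec.omega_max, spec.table_points)
    return TabulatedDensity(omega_grid=grid, j_values=_peaks_density(spec.peaks, grid))


def generate_fixture(spec: FixtureSpec, outdir) -> tuple[str, str]:
    """Write exciton + spectral-density files; deterministic and re-runnable."""
    os.makedirs(outdir, exist_ok=True)
    system = random_exciton_system(spec)
    exciton_path = os.path.join(outdir, "exciton.txt")
    write_exciton_file(system, exciton_path)
    sd_path = os.path.join(outdir, "spectral_density.txt")
    if spec.bath_kind == "drude":
        grid = np.linspace(spec.omega_min, spec.omega_max, spec.table_points)
        vals = DrudeLorentzDensity(spec.lambda_reorg, spec.gamma)(grid)
    else:
        grid = np.linspace(spec.omega_min, spec.omega_max, spec.table_points)
        vals = _peaks_density(spec.peaks, grid)
    write_spectral_density_table(grid, vals, sd_path,
                                 header=f"synthetic {spec.bath_kind} density, seed {spec.seed}")
    return exciton_path, sd_path


def scan_fixture_spec(seed: int = 7) -> FixtureSpec:
    """Bath recipe of the reduced-scale 7-site temperature/rank scans.

    A three-peak structured density on [30, 300] cm^-1 with total
    reorganization energy of roughly 20 cm^-1, discretized into 10 modes
    per site; the matching electronic part is :func:`fmo_like_system`.
    """
    return FixtureSpec(seed=seed)
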