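"""Frenkel exciton aggregate and harmonic-bath discretization.

The aggregate Hamiltonian in the one-excitation manifold is

    H = sum_n eps_n |n><n| - sum_{n!=m} J_nm |n><m|
        + sum_k w_k a_k^dag a_k - sum_{kn} (g_kn/sqrt2) |n><n| (a_k + a_k^dag)

with site energies eps_n, electronic couplings J_nm and linear
electron-phonon couplings g_kn (all in cm^-1).  A continuous bath spectral
density J(w) is represented as a finite set of modes through
J(w) = sum_k g_k^2 delta(w - w_k), inverted on a uniform frequency grid with
g_k^2 = J(w_k) * dw.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExcitonSystem",
    "SpectralDensity",
    "DrudeLorentzDensity",
    "TabulatedDensity",
    "BathDiscretization",
    "build_exciton_system",
    "evaluate_spectral_density",
    "discretize_spectral_density",
    "read_exciton_file",
    "write_exciton_file",
    "read_spectral_density_table",
    "write_spectral_density_table",
]


@dataclass(frozen=True)
class ExcitonSystem:
    """Electronic part of the aggregate: site energies and couplings (cm^-1).

    ``couplings`` is symmetric with an exactly zero diagonal; site energies
    live only in ``site_energies``.
    """

    site_energies: np.ndarray
    couplings: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.site_energies)

    def electronic_matrix(self) -> np.ndarray:
        """Dense one-exciton Hamiltonian: diag(eps) - J (cm^-1)."""
        return np.diag(self.site_energies) - self.couplings


def build_exciton_system(site_energies, couplings) -> ExcitonSystem:
    """Validate and construct an :class:`ExcitonSystem`.

    Couplings asymmetric by more than 1e-9 (absolute, relative to the largest
    entry) are rejected; smaller asymmetries are symmetrized.  A nonzero
    diagonal is rejected: site energies belong in ``site_energies``.
    """
    eps = np.asarray(site_energies, dtype=float).ravel()
    j = np.asarray(couplings, dtype=float)
    if eps.size < 1:
        raise ValueError("need at least one site")
    if j.ndim != 2 or j.shape[0] != j.shape[1]:
        raise ValueError(f"couplings must be square, got shape {j.shape}")
    if j.shape[0] != eps.size:
        raise ValueError(
            f"dimension mismatch: {eps.size} site energies vs "
            f"{j.shape[0]}x{j.shape[1]} coupling matrix"
        )
    scale = max(np.abs(j).max(), 1.0)
    asym = np.abs(j - j.T).max()
    if asym > 1e-9 * scale:
        raise ValueError(f"coupling matrix asymmetric beyond tolerance: {asym:g}")
    if np.abs(np.diag(j)).max() > 0.0:
        raise ValueError("coupling diagonal must be zero; put site energies in site_energies")
    j = 0.5 * (j + j.T)
    np.fill_diagonal(j, 0.0)
    eps.setflags(write=False)
    j.setflags(write=False)
    return ExcitonSystem(site_energies=eps, couplings=j)


class SpectralDensity:
    """Base class for bath spectral densities J(w) >= 0 (cm^-1 vs cm^-1)."""

    def __call__(self, omega):
        raise NotImplementedError


@dataclass(frozen=True)
class DrudeLorentzDensity(SpectralDensity):
    """Overdamped Drude-Lorentz density J(w) = 2*gamma*lambda*w/(gamma^2+w^2)."""

    lambda_reorg: float
    gamma: float

    def __post_init__(self):
        if self.lambda_reorg < 0 or self.gamma <= 0:
            raise ValueError("require lambda_reorg >= 0 and gamma > 0")

    def __call__(self, omega):
        omega = np.asarray(omega, dtype=float)
        return 2.0 * self.gamma * self.lambda_reorg * omega / (self.gamma**2 + omega**2)


@dataclass(frozen=True)
class TabulatedDensity(SpectralDensity):
    """Spectral density given on a grid; linear interpolation, zero outside."""

    omega_grid: np.ndarray
    j_values: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.omega_grid, dtype=float).ravel()
        j = np.asarray(self.j_values, dtype=float).ravel()
        if w.size != j.size or w.size < 2:
            raise ValueError("omega_grid and j_values must have equal length >= 2")
        if np.any(np.diff(w) <= 0):
            raise ValueError("omega_grid must be strictly increasing")
        if np.any(j < 0):
            raise ValueError("tabulated J(w) must be nonnegative")
        object.__setattr__(self, "omega_grid", w)
        object.__setattr__(self, "j_values", j)

    def __call__(self, omega):
        return np.interp(omega, self.omega_grid, self.j_values, left=0.0, right=0.0)


def evaluate_spectral_density(sd: SpectralDensity, omega):
    """Evaluate J(omega); nonnegative for omega > 0, zero outside a table."""
    return sd(omega)


@dataclass(frozen=True)
class BathDiscretization:
    """Discrete bath: frequencies w_k > 0 (strictly increasing), couplings g_k >= 0."""

    frequencies: np.ndarray
    couplings: np.ndarray
    spacing: float
    rule: str = "endpoint"

    def __post_init__(self):
        w = np.asarray(self.frequencies, dtype=float).ravel()
        g = np.asarray(self.couplings, dtype=float).ravel()
        if w.size != g.size:
            raise ValueError("frequencies and couplings length mismatch")
        if np.any(w <= 0):
            raise ValueError("bath frequencies must be strictly positive")
        if np.any(np.diff(w) <= 0):
            raise ValueError("bath frequencies must be strictly increasing")
        if np.any(g < 0):
            raise ValueError("bath couplings must be nonnegative")
        object.__setattr__(self, "frequencies", w)
        object.__setattr__(self, "couplings", g)

    @property
    def n_modes_per_site(self) -> int:
        return len(self.frequencies)

    def total_coupling_power(self) -> float:
        """sum_k g_k^2, the quadrature approximation of int J(w) dw."""
        return float(np.sum(self.couplings**2))

    def reorganization_energy(self) -> float:
        """sum_k g_k^2/(2 w_k): polaron shift of a single displaced site."""
        return float(np.sum(self.couplings**2 / (2.0 * self.frequencies)))


def discretize_spectral_density(
    sd: SpectralDensity,
    n_modes: int,
    omega_min: float,
    omega_max: float,
    rule: str = "endpoint",
) -> BathDiscretization:
    """Uniform-grid discretization of a spectral density into N explicit modes.

    With dw = (omega_max - omega_min)/N the grid is

    * ``endpoint`` (default): w_k = omega_min + (k-1) dw, k = 1..N, so that
      omega_min itself is a realized mode frequency;
    * ``midpoint``: w_k = omega_min + (k-1/2) dw.

    Couplings follow the bin-integral weighting g_k^2 = J(w_k) dw, consistent
    with reading J(w) = sum_k g_k^2 delta(w - w_k) as a quadrature of the
    continuous density.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if not (0.0 < omega_min < omega_max):
        raise ValueError("require 0 < omega_min < omega_max (zero-frequency bosons are ill-defined)")
    if rule not in ("endpoint", "midpoint"):
        raise ValueError(f"unknown grid rule {rule!r}")
    dw = (omega_max - omega_min) / n_modes
    k = np.arange(n_modes, dtype=float)
    offset = 0.0 if rule == "endpoint" else 0.5
    freqs = omega_min + (k + offset) * dw
    jvals = np.asarray(sd(freqs), dtype=float)
    if np.any(jvals < -1e-12):
        raise ValueError("spectral density evaluated negative on the grid")
    g = np.sqrt(np.clip(jvals, 0.0, None) * dw)
    return BathDiscretization(frequencies=freqs, couplings=g, spacing=dw, rule=rule)


# ---------------------------------------------------------------------------
# plain-text file formats


def read_exciton_file(path) -> ExcitonSystem:
    """Read an exciton file: n_sites, then the energies, then the J matrix rows."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"exciton file not found: {path}")
    with open(path) as fh:
        tokens = []
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.replace(",", " ").split())
    if not tokens:
        raise ValueError(f"empty exciton file: {path}")
    n = int(tokens[0])
    need = 1 + n + n * n
    if len(tokens) != need:
        raise ValueError(f"exciton file {path}: expected {need} numbers for n_sites={n}, got {len(tokens)}")
    vals = np.asarray([float(t) for t in tokens[1:]], dtype=float)
    return build_exciton_system(vals[:n], vals[n:].reshape(n, n))


def write_exciton_file(system: ExcitonSystem, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{system.n_sites}\n")
        fh.write(" ".join(f"{e:.12g}" for e in system.site_energies) + "\n")
        for row in system.couplings:
            fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")


def read_spectral_density_table(path) -> TabulatedDensity:
    """Two-column text table: omega (cm^-1), J(omega) (cm^-1); '#' comments."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"spectral-density file not found: {path}")
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"bad spectral-density line: {line!r}")
            rows.append((float(parts[0]), float(parts[1])))
    if len(rows) < 2:
        raise ValueError(f"spectral-density table {path} needs >= 2 rows")
    arr = np.asarray(rows, dtype=float)
    return TabulatedDensity(omega_grid=arr[:, 0], j_values=arr[:, 1])


def write_spectral_density_table(omega, j_values, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for w, j in zip(np.ravel(omega), np.ravel(j_values)):
            fh.write(f"{w:.12g} {j:.12g}\n")
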