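"""Dense-basis reference dynamics for small exciton-phonon instances.

Two independent routes to the same thermal expectation values:

* :func:`thermal_trace_dynamics` evaluates the canonical trace directly,
  <A(t)> = Tr{A(t) rho(0)} with rho(0) = |e><e| (x) rho_vib, by propagating
  every thermally occupied vibrational basis state of the bare Hamiltonian
  and Boltzmann-averaging the expectation values;

* :func:`dense_tfd_dynamics` propagates the single pure state |e>|0> under
  the dense doubled-space thermal Hamiltonian.

Their numerical agreement (with mutually converged boson truncations) is the
equivalence theorem this package rests on; both also serve as oracles for
the tensor-train propagation.  Everything here scales exponentially with the
number of modes and exists solely for verification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import reduce
from typing import Sequence

import numpy as np
import scipy.integrate

from .exciton_model import BathDiscretization, ExcitonSystem
from .thermofield import ThermalHamiltonian, _per_site_baths, build_thermal_hamiltonian
from .units import CM1_TO_RAD_FS, beta_cm

__all__ = [
    "DenseModel",
    "dense_exciton_hamiltonian",
    "dense_thermal_hamiltonian",
    "thermal_trace_dynamics",
    "thermal_trace_populations",
    "dense_tfd_dynamics",
    "dense_tfd_populations",
]

_DIM_CAP = 20_000


@dataclass(frozen=True)
class DenseModel:
    """Dense Hamiltonian over (electronic x truncated boson) product basis."""

    hamiltonian: np.ndarray          # cm^-1
    dims: tuple[int, ...]            # subsystem dims, electronic first
    mode_frequencies: np.ndarray     # signed frequency per boson subsystem
    couplings: np.ndarray            # linear coupling per boson subsystem
    sites: np.ndarray                # electronic site each boson couples to

    @property
    def dim(self) -> int:
        return self.hamiltonian.shape[0]


def _number_op(n):
    return np.diag(np.arange(n, dtype=float))


def _x_op(n):
    a = np.diag(np.sqrt(np.arange(1, n, dtype=float)), 1)
    return a + a.T


def _embed(dims: Sequence[int], factors: dict[int, np.ndarray]) -> np.ndarray:
    mats = [factors.get(k, np.eye(d)) for k, d in enumerate(dims)]
    return reduce(np.kron, mats)


def _build_dense(system: ExcitonSystem, coords, levels, dim_cap) -> DenseModel:
    """coords: sequence of (signed_omega, coupling, site); electronic first."""
    levels = np.asarray(levels, dtype=int).ravel()
    if levels.size != len(coords):
        raise ValueError("need one truncation level per boson coordinate")
    dims = (system.n_sites, *map(int, levels))
    dim = int(np.prod(dims))
    if dim > dim_cap:
        raise ValueError(f"dense dimension {dim} exceeds cap {dim_cap}")
    h = _embed(dims, {0: system.electronic_matrix()}).astype(complex)
    for j, (sw, g, site) in enumerate(coords):
        nb = dims[j + 1]
        h += sw * _embed(dims, {j + 1: _number_op(nb)})
        if g != 0.0:
            proj = np.zeros((system.n_sites, system.n_sites))
            proj[site, site] = 1.0
            h += (-g / np.sqrt(2.0)) * _embed(dims, {0: proj, j + 1: _x_op(nb)})
    if np.abs(h - h.conj().T).max() > 1e-10 * max(1.0, np.abs(h).max()):
        raise AssertionError("dense Hamiltonian not Hermitian")
    return DenseModel(
        hamiltonian=h, dims=dims,
        mode_frequencies=np.asarray([c[0] for c in coords], dtype=float),
        couplings=np.asarray([c[1] for c in coords], dtype=float),
        sites=np.asarray([c[2] for c in coords], dtype=int),
    )


def dense_exciton_hamiltonian(system: ExcitonSystem, bath, boson_levels, dim_cap=_DIM_CAP) -> DenseModel:
    """Dense bare (physical-space) exciton-phonon Hamiltonian."""
    baths = _per_site_baths(system, bath)
    coords = []
    for n, b in enumerate(baths):
        if b is None:
            continue
        for k in range(b.n_modes_per_site):
            coords.append((b.frequencies[k], b.couplings[k], n))
    levels = _expand_levels(boson_levels, len(coords))
    return _build_dense(system, coords, levels, dim_cap)


def dense_thermal_hamiltonian(thermal: ThermalHamiltonian, boson_levels, dim_cap=_DIM_CAP) -> DenseModel:
    """Dense doubled-space thermal Hamiltonian (independent of the MPO path)."""
    coords = [(c.signed_omega, c.coupling, c.site) for c in thermal.coordinates]
    levels = _expand_levels(boson_levels, len(coords))
    return _build_dense(thermal.system, coords, levels, dim_cap)


def _expand_levels(boson_levels, n):
    if np.isscalar(boson_levels):
        return np.full(n, int(boson_levels))
    return np.asarray(boson_levels, dtype=int).ravel()


def _promote_observable(obs: np.ndarray, model: DenseModel) -> np.ndarray:
    obs = np.asarray(obs)
    if obs.shape == (model.dim, model.dim):
        return obs
    if obs.shape == (model.dims[0], model.dims[0]):
        return _embed(model.dims, {0: obs})
    raise ValueError(f"observable shape {obs.shape} fits neither electronic nor full space")


def _propagate_columns(model: DenseModel, psi0: np.ndarray, times, method: str) -> list[np.ndarray]:
    """Return psi(t) (dim x n_states) for each requested time."""
    h = model.hamiltonian
    if method == "eig":
        evals, vecs = np.linalg.eigh(h)
        coeff = vecs.conj().T @ psi0
        return [vecs @ (np.exp(-1j * evals * CM1_TO_RAD_FS * t)[:, None] * coeff) for t in times]
    if method == "ode":
        def rhs(t, y):
            psi = y.reshape(h.shape[0], -1)
            return (-1j * CM1_TO_RAD_FS) * (h @ psi).ravel()
        sol = scipy.integrate.solve_ivp(
            rhs, (0.0, float(max(times))), psi0.astype(complex).ravel(),
            t_eval=times, rtol=1e-10, atol=1e-12, method="DOP853",
        )
        if not sol.success:
            raise RuntimeError(f"ODE propagation failed: {sol.message}")
        return [sol.y[:, i].reshape(psi0.shape) for i in range(len(times))]
    raise ValueError(f"unknown propagation method {method!r}")


def _vib_boltzmann(freqs: np.ndarray, levels: np.ndarray, temperature: float,
                   weight_floor: float, tail_warn: float):
    """Occupation-basis Boltzmann weights over the truncated uncoupled modes.

    Returns (multi-indices, weights).  The discarded Boltzmann mass of the
    truncation is estimated from the exact geometric partition sums and a
    warning is raised if it exceeds ``tail_warn``.
    """
    beta = beta_cm(temperature)
    if np.isinf(beta):
        return [tuple([0] * len(freqs))], np.asarray([1.0])
    qs = [np.exp(-beta * w * np.arange(nb)) for w, nb in zip(freqs, levels)]
    tail = 1.0 - np.prod([np.sum(q) * (1.0 - np.exp(-beta * w))
                          for q, w in zip(qs, freqs)])
    if tail > tail_warn:
        warnings.warn(
            f"truncated-basis Boltzmann tail {tail:.2e} exceeds {tail_warn:.0e}; "
            "raise the boson truncation", stacklevel=3)
    grids = np.meshgrid(*[np.arange(nb) for nb in levels], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    w = np.ones(idx.shape[0])
    for j, q in enumerate(qs):
        w *= q[idx[:, j]]
    w /= w.sum()
    keep = w > weight_floor
    idx, w = idx[keep], w[keep]
    return [tuple(row) for row in idx], w / w.sum()


def thermal_trace_dynamics(
    system: ExcitonSystem,
    bath,
    temperature: float,
    observables: Sequence[np.ndarray],
    times,
    boson_levels,
    initial_site: int = 0,
    method: str = "eig",
    dim_cap: int = _DIM_CAP,
    weight_floor: float = 1e-14,
    tail_warn: float = 1e-8,
) -> np.ndarray:
    """Boltzmann-trace reference: <A(t)> = Tr{A(t) |e><e| rho_vib}.

    Returns a (n_times x n_observables) real array.  ``method`` selects the
    propagation scheme: ``eig`` (eigendecomposition, reference) or ``ode``
    (high-order Runge-Kutta cross-check).
    """
    model = dense_exciton_hamiltonian(system, bath, boson_levels, dim_cap)
    times = np.asarray(times, dtype=float)
    levels = np.asarray(model.dims[1:], dtype=int)
    occupations, weights = _vib_boltzmann(
        model.mode_frequencies, levels, temperature, weight_floor, tail_warn)
    # flat index of |initial_site> (x) |occupation>
    strides = np.cumprod([1] + list(levels[::-1]))[::-1]
    psi0 = np.zeros((model.dim, len(occupations)), dtype=complex)
    for col, occ in enumerate(occupations):
        flat = initial_site * strides[0]
        for j, m in enumerate(occ):
            flat += m * strides[j + 1]
        psi0[flat, col] = 1.0
    obs_full = [_promote_observable(a, model) for a in observables]
    states = _propagate_columns(model, psi0, times, method)
    out = np.empty((len(times), len(obs_full)))
    for it, psi in enumerate(states):
        for ia, a in enumerate(obs_full):
            vals = np.einsum("ij,ij->j", psi.conj(), a @ psi).real
            out[it, ia] = float(np.dot(weights, vals))
    return out


def _site_projectors(n_sites: int) -> list[np.ndarray]:
    return [np.diag((np.arange(n_sites) == n).astype(float)) for n in range(n_sites)]


def thermal_trace_populations(system, bath, temperature, times, boson_levels, **kw) -> np.ndarray:
    """Site populations p_n(t) from the Boltzmann-trace route."""
    return thermal_trace_dynamics(
        system, bath, temperature, _site_projectors(system.n_sites),
        times, boson_levels, **kw)


def dense_tfd_dynamics(
    thermal: ThermalHamiltonian,
    observables: Sequence[np.ndarray],
    times,
    boson_levels,
    initial_site: int = 0,
    method: str = "eig",
    dim_cap: int = _DIM_CAP,
    gauge_shift: float = 0.0,
) -> np.ndarray:
    """Doubled-space reference: propagate |e>|0> under dense Hbar_theta.

    Electronic observables need no dressing (they commute with the Bogoliubov
    generator).  ``gauge_shift`` adds a constant to the tilde gauge
    Hamiltonian; expectation values must be invariant under it.
    """
    model = dense_thermal_hamiltonian(thermal, boson_levels, dim_cap)
    h = model.hamiltonian
    if gauge_shift:
        h = h - gauge_shift * np.eye(model.dim)
        model = DenseModel(h, model.dims, model.mode_frequencies, model.couplings, model.sites)
    times = np.asarray(times, dtype=float)
    psi0 = np.zeros((model.dim, 1), dtype=complex)
    strides = np.cumprod([1] + list(model.dims[:0:-1]))[::-1]
    psi0[initial_site * strides[0], 0] = 1.0
    obs_full = [_promote_observable(a, model) for a in observables]
    states = _propagate_columns(model, psi0, times, method)
    out = np.empty((len(times), len(obs_full)))
    for it, psi in enumerate(states):
        for ia, a in enumerate(obs_full):
            out[it, ia] = float(np.vdot(psi[:, 0], a @ psi[:, 0]).real)
    return out


def dense_tfd_populations(thermal, times, boson_levels, **kw) -> np.ndarray:
    """Site populations p_n(t) from the dense thermo-field route."""
    return dense_tfd_dynamics(
        thermal, _site_projectors(thermal.system.n_sites), times, boson_levels, **kw)
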