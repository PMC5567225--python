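"""Thermal Bogoliubov transformation and the doubled-space thermal Hamiltonian.

Thermo-field dynamics rewrites the canonical trace over vibrational states as
a pure-state expectation value in a doubled boson space: every physical mode
a_k acquires a fictitious "tilde" partner a~_k, and the thermal vacuum
|0(beta)> = e^{-iG}|0> is a two-mode squeezed state with mixing angle

    theta_k = arctanh(e^{-beta w_k / 2}).

Conjugating the (gauge-shifted) Hamiltonian with e^{iG} yields the thermal
Hamiltonian that drives a standard Schroedinger equation from the bare vacuum:

    Hbar_theta = H_el + sum_k w_k (a_k^dag a_k - a~_k^dag a~_k)
                 - sum_{kn} (g_kn/sqrt2) [ (a_k + a_k^dag) cosh(theta_k)
                                         + (a~_k + a~_k^dag) sinh(theta_k) ] |n><n|

Temperature enters only through the dressed couplings g cosh(theta) and
g sinh(theta); at T = 0 the tilde space decouples exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exciton_model import BathDiscretization, ExcitonSystem
from .units import beta_cm

__all__ = [
    "ThermalParameters",
    "BosonCoordinate",
    "ThermalHamiltonian",
    "DiscreteDensity",
    "mixing_angles",
    "build_thermal_hamiltonian",
    "effective_spectral_densities",
    "transform_boson_operator",
    "TILDE_PRUNE_PRESET",
]

#: convenience preset implementing the rule of thumb that high-frequency
#: modes need no tilde partner (sinh(theta) < 1e-3 dropped)
TILDE_PRUNE_PRESET = 1e-3


@dataclass(frozen=True)
class ThermalParameters:
    """Per-mode thermal mixing angles at a given temperature.

    cosh/sinh are computed directly from x = e^{-beta w/2} as
    cosh = 1/sqrt(1-x^2), sinh = x/sqrt(1-x^2), which stays finite for
    x -> 1 much longer than arctanh followed by sinh/cosh would.
    """

    temperature: float
    beta: float            # 1/cm^-1, inf at T = 0
    frequencies: np.ndarray
    thetas: np.ndarray
    sinh_thetas: np.ndarray
    cosh_thetas: np.ndarray

    def occupation(self) -> np.ndarray:
        """Bose-Einstein occupation n(w) = sinh^2(theta) of each mode."""
        return self.sinh_thetas**2


def mixing_angles(frequencies, temperature: float) -> ThermalParameters:
    """Thermal mixing angles theta_k = arctanh(e^{-beta w_k/2}).

    T = 0 is the exact limit theta = 0.  Zero or negative frequencies are
    rejected (the arctanh argument would reach 1).
    """
    w = np.asarray(frequencies, dtype=float).ravel()
    if np.any(w <= 0):
        raise ValueError("mixing angles require strictly positive frequencies")
    beta = beta_cm(temperature)
    if math.isinf(beta):
        x = np.zeros_like(w)
    else:
        x = np.exp(-0.5 * beta * w)
    sech = np.sqrt(1.0 - x * x)  # 1/cosh(theta)
    cosh = 1.0 / sech
    sinh = x / sech
    theta = np.arctanh(x)
    return ThermalParameters(
        temperature=temperature, beta=beta, frequencies=w,
        thetas=theta, sinh_thetas=sinh, cosh_thetas=cosh,
    )


@dataclass(frozen=True)
class BosonCoordinate:
    """One retained vibrational coordinate of the doubled space.

    ``omega`` is the positive mode frequency; the number operator enters the
    thermal Hamiltonian with +omega for physical and -omega for tilde
    coordinates.  ``coupling`` is the dressed linear coupling (g cosh(theta)
    or g sinh(theta)); the Hamiltonian term is
    -(coupling/sqrt2) (b + b^dag) |site><site|.
    """

    site: int
    omega: float
    coupling: float
    is_tilde: bool
    mode_index: int  # index of the parent mode within its site's bath

    @property
    def signed_omega(self) -> float:
        return -self.omega if self.is_tilde else self.omega


@dataclass(frozen=True)
class ThermalHamiltonian:
    """Term list of the doubled-space thermal Hamiltonian Hbar_theta."""

    system: ExcitonSystem
    coordinates: tuple[BosonCoordinate, ...]
    temperature: float
    baths: tuple[BathDiscretization | None, ...]
    tilde_prune_threshold: float

    @property
    def n_coordinates(self) -> int:
        return len(self.coordinates)

    @property
    def tilde_mask(self) -> np.ndarray:
        return np.asarray([c.is_tilde for c in self.coordinates], dtype=bool)

    def mode_frequencies(self) -> np.ndarray:
        """Signed number-operator frequencies (+w physical, -w tilde), cm^-1."""
        return np.asarray([c.signed_omega for c in self.coordinates], dtype=float)

    def dressed_couplings(self) -> np.ndarray:
        return np.asarray([c.coupling for c in self.coordinates], dtype=float)


def _per_site_baths(system: ExcitonSystem, bath) -> tuple:
    if bath is None:
        return tuple([None] * system.n_sites)
    if isinstance(bath, BathDiscretization):
        return tuple([bath] * system.n_sites)
    baths = tuple(bath)
    if len(baths) != system.n_sites:
        raise ValueError(f"need one bath (or None) per site: got {len(baths)} for {system.n_sites} sites")
    return baths


def build_thermal_hamiltonian(
    system: ExcitonSystem,
    bath: BathDiscretization | Sequence[BathDiscretization | None] | None,
    temperature: float,
    tilde_prune_threshold: float = 0.0,
) -> ThermalHamiltonian:
    """Assemble the doubled-space thermal Hamiltonian term list.

    ``bath`` may be a single :class:`BathDiscretization` replicated over all
    sites (identical uncorrelated baths), or a per-site sequence (``None``
    for an uncoupled site).  A tilde coordinate is dropped when
    sinh(theta_k) < ``tilde_prune_threshold``; the default 0 keeps every
    tilde partner, :data:`TILDE_PRUNE_PRESET` prunes the effectively
    decoupled high-frequency ones.
    """
    if tilde_prune_threshold < 0:
        raise ValueError("tilde_prune_threshold must be >= 0")
    baths = _per_site_baths(system, bath)
    coords: list[BosonCoordinate] = []
    for n, b in enumerate(baths):
        if b is None or b.n_modes_per_site == 0:
            continue
        tp = mixing_angles(b.frequencies, temperature)
        for k in range(b.n_modes_per_site):
            g = b.couplings[k]
            w = b.frequencies[k]
            coords.append(BosonCoordinate(
                site=n, omega=w, coupling=g * tp.cosh_thetas[k],
                is_tilde=False, mode_index=k,
            ))
            if tp.sinh_thetas[k] >= tilde_prune_threshold:
                coords.append(BosonCoordinate(
                    site=n, omega=w, coupling=g * tp.sinh_thetas[k],
                    is_tilde=True, mode_index=k,
                ))
    return ThermalHamiltonian(
        system=system, coordinates=tuple(coords), temperature=temperature,
        baths=baths, tilde_prune_threshold=tilde_prune_threshold,
    )


@dataclass(frozen=True)
class DiscreteDensity:
    """Discrete spectral weights: weight w_k^2-like masses at frequencies."""

    frequencies: np.ndarray   # signed axis: tilde weights sit at -w_k
    weights: np.ndarray


def effective_spectral_densities(
    bath: BathDiscretization, temperature: float
) -> tuple[DiscreteDensity, DiscreteDensity]:
    """Temperature-dressed discrete densities J_p (physical) and J_t (tilde).

    J_p carries weights (g_k cosh theta_k)^2 at +w_k; J_t carries
    (g_k sinh theta_k)^2 indexed on the negative frequency axis at -w_k.
    At T = 0, J_p reduces to the bare weights and J_t vanishes identically.
    """
    tp = mixing_angles(bath.frequencies, temperature)
    jp = DiscreteDensity(
        frequencies=bath.frequencies.copy(),
        weights=(bath.couplings * tp.cosh_thetas) ** 2,
    )
    jt = DiscreteDensity(
        frequencies=-bath.frequencies.copy(),
        weights=(bath.couplings * tp.sinh_thetas) ** 2,
    )
    return jp, jt


def transform_boson_operator(theta: float, which: str) -> tuple[tuple[str, float], tuple[str, float]]:
    """Heisenberg-like transform of an annihilation operator under e^{iG}.

    Returns the two-term linear combination

        e^{iG} a e^{-iG}  = a cosh(theta) + a~^dag sinh(theta)   (physical)
        e^{iG} a~ e^{-iG} = a~ cosh(theta) + a^dag sinh(theta)   (tilde)

    as ``((label, coeff), (label, coeff))`` descriptors.  Purely electronic
    operators commute with G and transform to themselves, which is why site
    populations need no dressing.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    c, s = math.cosh(theta), math.sinh(theta)
    if which == "physical":
        return (("a", c), ("tilde_a_dag", s))
    if which == "tilde":
        return (("tilde_a", c), ("a_dag", s))
    raise ValueError(f"which must be 'physical' or 'tilde', got {which!r}")
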