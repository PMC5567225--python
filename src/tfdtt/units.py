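"""Unit conventions.

All user-facing energies and frequencies are wavenumbers (cm^-1); time is
femtoseconds; hbar = 1.  A Hamiltonian H given in cm^-1 generates the phase
exp(-i * H * CM1_TO_RAD_FS * t_fs).
"""

import math

#: speed of light in cm/fs
C_CM_PER_FS = 2.99792458e-5

#: conversion factor: angular frequency in rad/fs per cm^-1
CM1_TO_RAD_FS = 2.0 * math.pi * C_CM_PER_FS

#: Boltzmann constant in cm^-1 per Kelvin
KB_CM1_PER_K = 0.6950348


def beta_cm(temperature: float) -> float:
    """Inverse temperature 1/(k_B T) in 1/cm^-1; +inf at T = 0."""
    if temperature < 0:
        raise ValueError(f"temperature must be >= 0 K, got {temperature}")
    if temperature == 0:
        return math.inf
    return 1.0 / (KB_CM1_PER_K * temperature)
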