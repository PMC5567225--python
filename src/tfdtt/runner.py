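"""End-to-end experiment runner: config -> discretize -> thermalize -> TT ->
propagate -> trajectory/diagnostic files.

A run directory is self-describing: it receives the trajectory table, the
effective spectral densities, the fully resolved configuration and a staged
log, so a run can be repeated exactly from its own outputs.
"""

from __future__ import annotations

import dataclasses
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from .exciton_model import (
    DrudeLorentzDensity,
    discretize_spectral_density,
    read_exciton_file,
    read_spectral_density_table,
    write_spectral_density_table,
)
from .observables import Trajectory, write_trajectory_tsv
from .tdvp import PropagationConfig, propagate, rank_convergence_scan
from .tensor_train import (
    default_boson_levels,
    default_site_ordering,
    hamiltonian_to_tt_operator,
    vacuum_product_state,
)
from .thermofield import build_thermal_hamiltonian, effective_spectral_densities

__all__ = ["RunConfig", "load_run_config", "run_experiment", "scan_temperatures"]


@dataclass
class RunConfig:
    """Validated, fully explicit description of one propagation run."""

    exciton_file: str
    outdir: str
    spectral_density_file: str | None = None
    drude_lambda: float | None = None
    drude_gamma: float | None = None
    temperature: float = 300.0
    n_modes: int = 10
    omega_min: float = 30.0
    omega_max: float = 300.0
    grid_rule: str = "endpoint"
    initial_site: int = 1            # 1-based site index
    tilde_prune_threshold: float = 0.0
    boson_c: float = 3.0
    boson_min: int = 4
    boson_max: int | None = 8
    dt: float = 2.0
    t_final: float = 200.0
    max_rank: int = 8
    krylov_dim: int = 15
    krylov_tol: float = 1e-10
    observable_stride: int = 1
    dense_expm_cutoff: int = 64
    rank_list: list[int] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.spectral_density_file is None and (
            self.drude_lambda is None or self.drude_gamma is None
        ):
            raise ValueError("config needs spectral_density_file or drude_lambda + drude_gamma")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0 K")
        if self.initial_site < 1:
            raise ValueError("initial_site is 1-based and must be >= 1")
        if not (0 < self.omega_min < self.omega_max):
            raise ValueError("require 0 < omega_min < omega_max")
        # PropagationConfig re-validates the time-grid fields
        self.propagation_config()

    def propagation_config(self) -> PropagationConfig:
        return PropagationConfig(
            dt=self.dt, t_final=self.t_final, max_rank=self.max_rank,
            krylov_dim=self.krylov_dim, krylov_tol=self.krylov_tol,
            observable_stride=self.observable_stride,
            dense_expm_cutoff=self.dense_expm_cutoff,
        )


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_run_config(path, **overrides) -> RunConfig:
    """Load a YAML run config; keyword overrides take precedence."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def _spectral_density(config: RunConfig):
    if config.spectral_density_file is not None:
        return read_spectral_density_table(config.spectral_density_file)
    return DrudeLorentzDensity(config.drude_lambda, config.drude_gamma)


def run_experiment(config: RunConfig) -> Trajectory:
    """Full pipeline for one temperature; writes all outputs to config.outdir."""
    os.makedirs(config.outdir, exist_ok=True)
    log_path = os.path.join(config.outdir, "log.txt")
    t0 = time.time()

    def log(msg):
        line = f"[{time.time() - t0:8.2f}s] {msg}"
        with open(log_path, "a") as fh:
            fh.write(line + "\n")

    with open(os.path.join(config.outdir, "config_resolved.yaml"), "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)

    log("reading inputs")
    system = read_exciton_file(config.exciton_file)
    if config.initial_site > system.n_sites:
        raise ValueError(f"initial_site {config.initial_site} exceeds n_sites {system.n_sites}")
    sd = _spectral_density(config)

    log(f"discretizing density: N={config.n_modes} on [{config.omega_min}, {config.omega_max}] cm^-1")
    bath = discretize_spectral_density(
        sd, config.n_modes, config.omega_min, config.omega_max, rule=config.grid_rule)

    log(f"thermal Hamiltonian at T={config.temperature} K "
        f"(tilde prune threshold {config.tilde_prune_threshold:g})")
    thermal = build_thermal_hamiltonian(
        system, bath, config.temperature, config.tilde_prune_threshold)
    log(f"retained vibrational coordinates: {thermal.n_coordinates} "
        f"({int(np.sum(~thermal.tilde_mask))} physical + {int(np.sum(thermal.tilde_mask))} tilde)")

    jp, jt = effective_spectral_densities(bath, config.temperature)
    write_spectral_density_table(
        jp.frequencies, jp.weights, os.path.join(config.outdir, "j_physical.txt"),
        header="effective physical weights (g cosh theta)^2 at +omega")
    write_spectral_density_table(
        jt.frequencies[::-1], jt.weights[::-1],
        os.path.join(config.outdir, "j_tilde.txt"),
        header="effective tilde weights (g sinh theta)^2 at -omega")

    ordering = default_site_ordering(thermal)
    levels = default_boson_levels(
        thermal, c=config.boson_c, n_min=config.boson_min, n_max=config.boson_max)
    log(f"boson levels: min {levels.min() if len(levels) else 0}, "
        f"max {levels.max() if len(levels) else 0}")
    op = hamiltonian_to_tt_operator(thermal, ordering, levels)

    state0 = vacuum_product_state(ordering, levels, system.n_sites,
                                  initial_site=config.initial_site - 1)

    pcfg = config.propagation_config()
    log(f"propagating: dt={pcfg.dt} fs, t_final={pcfg.t_final} fs, max_rank={pcfg.max_rank}")
    traj = propagate(state0, op, pcfg, ordering)
    write_trajectory_tsv(traj, os.path.join(config.outdir, "trajectory.tsv"))
    log(f"done: final IPR {traj.ipr[-1]:.4f}, norm drift {abs(traj.norm[-1] - 1):.2e}, "
        f"energy drift {abs(traj.energy[-1] - traj.energy[0]):.2e} cm^-1")

    if config.rank_list:
        log(f"rank convergence scan over {config.rank_list}")
        report = rank_convergence_scan(state0, op, pcfg, config.rank_list, ordering,
                                       keep_trajectories=False)
        with open(os.path.join(config.outdir, "rank_convergence.tsv"), "w") as fh:
            fh.write("rank_low\trank_high\tmax_population_diff\n")
            for (a, b), dmax in zip(
                zip(report.ranks, report.ranks[1:]), report.max_population_diffs
            ):
                fh.write(f"{a}\t{b}\t{dmax:.6e}\n")
        log(f"rank scan diffs: {report.max_population_diffs}")
    return traj


def scan_temperatures(config: RunConfig, temperatures) -> dict[float, Trajectory]:
    """Run the same experiment at several temperatures, one subdirectory each."""
    out = {}
    base = config.outdir
    for t in temperatures:
        sub = dataclasses.replace(
            config, temperature=float(t),
            outdir=os.path.join(base, f"T{float(t):g}K"))
        out[float(t)] = run_experiment(sub)
    return out
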