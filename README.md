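# tfdtt — finite-temperature exciton dynamics with thermo-field tensor trains

`tfdtt` simulates the quantum dynamics of Frenkel exciton–phonon aggregates
(light-harvesting complexes, molecular crystals, model dimers) at finite
temperature, for people who want numerically controlled wavefunction
dynamics — populations, coherent beatings, exciton delocalization — without
moving to density-matrix (Liouville-space) machinery.

## The method

A one-exciton aggregate coupled linearly to harmonic baths is described by

    H = Σₙ εₙ|n⟩⟨n| − Σ_{n≠m} J_{nm}|n⟩⟨m| + Σ_k ω_k a†_k a_k
        − Σ_{kn} (g_{kn}/√2) |n⟩⟨n| (a_k + a†_k)

with all energies in cm⁻¹.  A continuous bath spectral density J(ω) is
discretized on a uniform grid into explicit modes via g_k² = J(ω_k)Δω.

Thermal averages ⟨A(t)⟩ = Tr{A(t)ρ(0)} with ρ(0) = |e⟩⟨e| ⊗ ρ_vib are
rewritten, by the thermal Bogoliubov transformation of thermo-field
dynamics, as a pure-state expectation ⟨φ(t)|A_θ|φ(t)⟩.  Every mode acquires
a fictitious "tilde" partner ãₖ; the mixing angle is

    θ_k = arctanh(e^{−βω_k/2}),   sinh²θ_k = 1/(e^{βω_k} − 1),

and |φ(t)⟩ evolves from the bare vacuum |e⟩|0⟩ under the thermal Hamiltonian

    H̄_θ = Σₙ εₙ|n⟩⟨n| − Σ J_{nm}|n⟩⟨m| + Σ_k ω_k (a†a − ã†ã)
          − Σ_{kn} (g_{kn}/√2) { (a+a†) cosh θ_k + (ã+ã†) sinh θ_k } |n⟩⟨n|.

Temperature enters only through the dressed couplings g·coshθ and g·sinhθ;
at T = 0 the tilde space decouples exactly.  The doubled-space wavefunction
is stored as a tensor train (matrix product state) and propagated with the
second-order projector-splitting TDVP integrator; the Hamiltonian is an
exact finite-state-automaton MPO.  Site populations pₙ(t) and the inverse
participation ratio Π(t) = 1/Σₙ pₙ²(t) — the effective number of occupied
sites, between 1 (localized) and n_sites (uniform) — are read off the
propagated state.

Every piece is cross-checked against dense-basis oracles (`exact_oracle`):
the Boltzmann-trace dynamics and the doubled-space propagation agree to
better than 1e-6 on small fixtures, and the TT/TDVP trajectory matches the
dense reference to 1e-8 at full rank.

## Worked example

```python
import numpy as np
from tfdtt import *
from tfdtt.tensor_train import (default_boson_levels, default_site_ordering,
                                hamiltonian_to_tt_operator, vacuum_product_state)

# thermalized dimer: 100 cm^-1 gap and coupling, one 180 cm^-1 mode on site 1
system = build_exciton_system([0.0, 100.0], [[0.0, 100.0], [100.0, 0.0]])
bath = BathDiscretization(frequencies=np.array([180.0]),
                          couplings=np.array([50.0]), spacing=1.0)
thermal = build_thermal_hamiltonian(system, [bath, None], temperature=300.0)

ordering = default_site_ordering(thermal)
levels = np.full(thermal.n_coordinates, 12)
op = hamiltonian_to_tt_operator(thermal, ordering, levels)
state0 = vacuum_product_state(ordering, levels, system.n_sites, initial_site=0)

cfg = PropagationConfig(dt=1.0, t_final=500.0, max_rank=16, observable_stride=100)
traj = propagate(state0, op, cfg, ordering)
for t, p, pi in zip(traj.times, traj.populations, traj.ipr):
    print(f"t={t:5.0f} fs  p1={p[0]:.4f}  p2={p[1]:.4f}  IPR={pi:.4f}")
```

prints

```
t=    0 fs  p1=1.0000  p2=0.0000  IPR=1.0000
t=  100 fs  p1=0.4778  p2=0.5222  IPR=1.9961
t=  200 fs  p1=0.3406  p2=0.6594  IPR=1.8155
t=  300 fs  p1=0.7511  p2=0.2489  IPR=1.5971
t=  400 fs  p1=0.7629  p2=0.2371  IPR=1.5669
t=  500 fs  p1=0.3469  p2=0.6531  IPR=1.8285
```

The excitation started on site 1 beats back and forth across the strongly
coupled dimer, modulated by the 180 cm⁻¹ mode; at 300 K the thermal
dressing (cosh θ = 1.32, sinh θ = 0.85 for this mode) redistributes the
electron-phonon coupling between the physical and tilde branches and damps
the beats relative to a T = 0 run.  The same numbers, within 1e-8, come out
of the dense doubled-space reference `dense_tfd_populations(thermal, times, 12)`.

The command-line interface exposes the same pipeline (`tfdtt run config.yaml`,
plus `discretize`, `thermalize`, `scan-ranks`, `scan-temperatures`,
`make-fixture`, `validate-oracle`); see `tfdtt --help`.

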