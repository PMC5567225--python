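# Methods

## Model

The package treats a Frenkel aggregate in its one-excitation manifold: sites
|n⟩ with energies εₙ, electronic couplings J_{nm} (entering the Hamiltonian
as −J_{nm}|n⟩⟨m|), and per-site harmonic baths coupled linearly through
−(g_{kn}/√2)(a_k + a†_k)|n⟩⟨n|.  All user-facing energies and frequencies
are wavenumbers (cm⁻¹); time is femtoseconds; ħ = 1; phases are generated
with ω[rad/fs] = 2πc·ω[cm⁻¹] and k_B = 0.6950348 cm⁻¹/K.

A continuous spectral density J(ω) — parametric Drude–Lorentz
2γλω/(γ²+ω²) or a two-column table with linear interpolation (zero outside
the tabulated support) — is mapped to explicit modes on a uniform grid.
The default grid places ω_min itself as a realized frequency
(ω_k = ω_min + (k−1)Δω, Δω = (ω_max − ω_min)/N); a midpoint rule is
available through `rule="midpoint"`.  Couplings follow the bin-integral
inversion g_k² = J(ω_k)Δω, so Σ g_k² approximates ∫J dω with the quadrature
error of the chosen rule; the inverse map from a density to couplings is a
convention, and this one reproduces the density's integral under grid
refinement.  ω_min must be strictly positive: a zero-frequency boson has no
well-defined thermal mixing angle.

By default a single bath discretization is replicated over all sites
(identical uncorrelated baths); per-site baths — including bare sites — are
supported by passing a sequence.

## Thermal doubling

Finite temperature is handled entirely in Hilbert space.  The canonical
average over vibrational states is converted into a single pure-state
evolution by doubling every mode with a tilde partner and applying the
thermal Bogoliubov transformation with mixing angle
θ_k = arctanh(e^{−βω_k/2}).  The propagated Hamiltonian carries +ω_k a†a for
physical and −ω_k ã†ã for tilde coordinates (the tilde gauge is fixed to the
free tilde Hamiltonian; the gauge only shifts a global phase, which the
tests verify) and the dressed couplings g coshθ (physical) and g sinhθ
(tilde).

Numerics: coshθ and sinhθ are computed directly from x = e^{−βω/2} as
1/√(1−x²) and x/√(1−x²), which is stable where arctanh followed by
sinh/cosh overflows (low ω at high T).  T = 0 is taken as the exact limit
θ = 0.  The Bogoliubov generator is never exponentiated numerically; every
transformed operator is assembled analytically from the two-term operator
transform.  sinh²θ_k equals the Bose occupation 1/(e^{βω_k}−1), which is
asserted to 1e-10 across a frequency–temperature grid.

Tilde pruning: a tilde coordinate is dropped when sinhθ_k falls below a
threshold.  The default threshold is 0 (keep everything — correctness
first); the preset `TILDE_PRUNE_PRESET = 1e-3` implements the observation
that high-frequency modes are effectively frozen and need no thermal
partner.  At T = 0 the preset removes the entire tilde space and the bare
Schrödinger dynamics is recovered; the suite checks this reduction at the
trajectory level.

## Tensor-train representation

The doubled-space wavefunction is a tensor train: order-3 cores
(r_{k−1}, n_k, r_k) with unit boundary ranks, storage Θ(d·n·r²).  The
electronic degree of freedom is one core of dimension n_sites (the
one-exciton basis), not a string of two-level cores.  The default chain
ordering puts the electronic core first, then per-site mode groups
ascending in frequency with each tilde coordinate adjacent to its physical
partner — the two couple through the same electronic projector, and
adjacency keeps the entanglement they generate local.  Alternative
orderings are injectable through `SiteOrdering`.

The Hamiltonian is built as an exact MPO by a finite-state automaton over
one-body terms and (electronic projector)⊗(displacement) two-body terms.
For the shipped orderings its bond dimension is n_sites + 2, independent of
chain length; no compression is applied, so the MPO equals the dense
Kronecker construction on small instances to 1e-10 (tested).

Boson basis sizes default to max(4, ⌈c(n̄_k+1)⌉+2) per coordinate with
c = 3 and n̄_k the Bose occupation of the parent mode: thermally excited
low-frequency modes need more levels.  An optional cap (`boson_max`,
default 8 in the run configuration) bounds the cost of reduced-scale runs;
convergence in both levels and rank is the user's responsibility and the
rank-scan tool exists for exactly that.

## Propagation

The integrator is the second-order symmetric single-site projector-splitting
TDVP scheme: a left-to-right sweep of half-step forward single-core
evolutions interleaved with half-step backward bond-matrix evolutions, then
the mirrored right-to-left sweep.  Effective Hamiltonians come from cached
left/right environment contractions of the MPO.  Local exponentials use a
Lanczos Krylov method with full reorthogonalization (default dimension 15,
tolerance 1e-10; non-convergence raises with a diagnostic) or an exact
dense exponential when the local dimension is at most `dense_expm_cutoff`
(default 64).  The default time step should satisfy dt·ω_max ≲ 0.5 rad;
the shipped configurations use 1–4 fs.

Ranks are fixed during a sweep.  Rank growth is handled by restarting from
a rank-enlarged state; the enlarged blocks are seeded with deterministic
noise of relative scale 1e-10 rather than exact zeros, because the
single-site scheme provably cannot rotate amplitude into an exactly zero
rank block (the environments restricted to it vanish).  The perturbation is
orders of magnitude below every tolerance used.

Properties verified by the suite: norm and energy are conserved to the
local-solver tolerance (|‖φ‖−1| < 1e-8 over hundreds of steps, relative
energy drift < 1e-6); halving dt reduces the self-convergence error about
fourfold; and when the ranks are full the trajectory coincides with dense
doubled-space propagation (the splitting is exact on a manifold containing
the solution), which pins the whole TT/TDVP stack against the dense oracle
at 1e-8.

Propagation aborts if |norm − 1| exceeds 1e-6 — with a Hermitian MPO this
only happens when the local solver tolerance is too loose for the step.

## Dense oracles

`exact_oracle` provides two independent small-system routes: (i) the
Boltzmann-trace dynamics — dense bare Hamiltonian, initial density
|e⟩⟨e| ⊗ ρ_vib with harmonic Boltzmann weights over the truncated
occupation basis, propagated by eigendecomposition (with a high-order ODE
integrator as a cross-check of the propagator itself) — and (ii) dense
doubled-space propagation of |e⟩|0⟩ under the thermal Hamiltonian.  Their
agreement (better than 1e-6 on the thermalized dimer over 500 fs, with
mutually converged truncations) is the numerical form of the equivalence
theorem the method rests on, and the cornerstone test of the repository.
The truncation's discarded Boltzmann mass is computed exactly from
geometric partition sums and warned about above 1e-8.  The harmonic
Boltzmann weight uses the standard e^{−βΣω a†a}; a zero-point reordering
constant cancels in the normalized trace.  The oracles are capped at a
dense dimension of 20,000 and exist solely for verification.

## Observables

Site populations are computed by gauging the state to the electronic core
and contracting that single core — the electronic projector commutes with
the Bogoliubov generator, so no thermal dressing is needed; the contraction
equals the MPO-projector expectation value to 1e-12 (tested).  The inverse
participation ratio Π = 1/Σpₙ² is permutation invariant, maximized by the
uniform distribution, and bounded by [1, n_sites].  Trajectories are
written as tab-separated tables (time_fs, p_1…p_n, ipr, norm, energy_cm1);
TT states serialize to a version-tagged single-archive checkpoint.

## Synthetic fixtures and what they do (not) show

The fixture generator produces two kinds of inputs.  Random aggregates
draw site energies and symmetric couplings from seeded normal
distributions — useful for property tests, byte-identical for identical
spec + seed.  The temperature/rank scans instead use a deterministic
synthetic 7-site Hamiltonian (`fmo_like_system`) with invented numbers but
the structural features of a 7-pigment light-harvesting monomer: a strongly
coupled site-1/2 dimer that receives the initial excitation, a low-energy
trap at site 3, and a secondary relay.  A purely random draw can land on a
weak 1–2 coupling and show no dimer beating at all, which would test
nothing; the scan fixture is chosen so that the phenomena under test —
coherent beating, thermal delocalization — are present in the model at all.

Structured densities are sums of positive Lorentzian peaks on a grid; the
scan density has three peaks on [30, 300] cm⁻¹ and a total reorganization
energy near 20 cm⁻¹, with 10 modes per site.  The scan runs 500 fs at
dt = 4 fs, rank 8, boson levels capped at 8 — problem sizes chosen so the
scan behaves like a desk-scale experiment.  What passing shows: the
terminal-time delocalization increases monotonically across {0, 77, 300} K,
dimer beats persist at all temperatures, and inter-rank differences shrink.
What it does not show: convergence at experimental scale (74 modes/site
from 2 cm⁻¹, ~1 ps horizons, ranks of order 40), where the bath's 2 cm⁻¹
edge is heavily thermally occupied and both basis sizes and ranks must be
raised until the solution stops moving.  The pipeline takes the same path
at that scale; only the configuration numbers change.

## Known limitations

- No two-exciton manifold, tree tensor networks, adaptive time stepping,
  imaginary-time propagation, or dissipative (Lindblad) terms — temperature
  enters only through the Hamiltonian.
- No correlated (cross-site) baths and no derivation of spectral densities
  from experiment or simulation; any tabulated density is accepted as-is.
- The single-site integrator keeps ranks fixed; badly underestimated ranks
  show up as rank-scan non-convergence rather than as a runtime error.
- The dense oracles scale exponentially with mode count and stop at a few
  modes.
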