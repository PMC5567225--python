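import numpy as np
import pytest

from tfdtt import (
    BathDiscretization,
    PropagationConfig,
    build_exciton_system,
    build_thermal_hamiltonian,
    default_site_ordering,
    densify,
    hamiltonian_to_tt_operator,
    propagate,
    rank_convergence_scan,
    tdvp_step,
    tt_product_state,
)
from tfdtt.exact_oracle import dense_tfd_populations
from tfdtt.tdvp import KrylovConvergenceError, NormDriftError, _lanczos_expm
from tfdtt.tensor_train import vacuum_product_state
from tfdtt.units import CM1_TO_RAD_FS


def _electronic_op(system):
    th = build_thermal_hamiltonian(system, None, 0.0)
    ordering = default_site_ordering(th)
    return th, ordering, hamiltonian_to_tt_operator(th, ordering, np.zeros(0, dtype=int))


@pytest.fixture
def dimer_tt_setup(dimer_system, dimer_baths):
    th = build_thermal_hamiltonian(dimer_system, dimer_baths, 300.0)
    ordering = default_site_ordering(th)
    nb = 8
    levels = np.full(th.n_coordinates, nb)
    op = hamiltonian_to_tt_operator(th, ordering, levels)
    state0 = vacuum_product_state(ordering, levels, 2, 0)
    return th, ordering, levels, op, state0


class TestTdvpStep:
    def test_zero_hamiltonian_leaves_state_unchanged(self):
        system = build_exciton_system([0.0, 0.0], np.zeros((2, 2)))
        _, _, op = _electronic_op(system)
        state = tt_product_state([np.array([0.6, 0.8])])
        out = tdvp_step(state, op, dt=5.0)
        np.testing.assert_allclose(densify(out), densify(state), atol=1e-13)

    def test_rabi_oscillation_closed_form(self):
        """Electronic-only dimer follows p2(t) = J^2/(J^2+d^2) sin^2(sqrt(J^2+d^2) t)."""
        eps1, eps2, j = 0.0, 100.0, 80.0
        system = build_exciton_system([eps1, eps2], [[0.0, j], [j, 0.0]])
        _, ordering, op = _electronic_op(system)
        state = tt_product_state([np.array([1.0, 0.0])])
        cfg = PropagationConfig(dt=0.5, t_final=200.0, max_rank=1, observable_stride=4)
        traj = propagate(state, op, cfg, ordering)
        delta = 0.5 * (eps1 - eps2) * CM1_TO_RAD_FS
        jr = j * CM1_TO_RAD_FS
        omega = np.sqrt(jr**2 + delta**2)
        p2 = (jr**2 / omega**2) * np.sin(omega * traj.times) ** 2
        np.testing.assert_allclose(traj.populations[:, 1], p2, atol=1e-8)

    def test_full_rank_matches_dense_tfd(self, dimer_tt_setup):
        """With full TT ranks the splitting integrator is exact: trajectory
        equals dense doubled-space propagation."""
        th, ordering, levels, op, state0 = dimer_tt_setup
        cfg = PropagationConfig(dt=1.0, t_final=100.0, max_rank=16,
                                observable_stride=5, dense_expm_cutoff=0,
                                krylov_dim=30, krylov_tol=1e-12)
        traj = propagate(state0, op, cfg, ordering)
        p_ref = dense_tfd_populations(th, traj.times, int(levels[0]))
        assert np.max(np.abs(traj.populations - p_ref)) < 1e-8

    def test_second_order_self_convergence(self, dimer_system):
        """Halving dt reduces the error vs a dt/8 reference about fourfold."""
        bath = BathDiscretization(frequencies=np.array([120.0, 220.0]),
                                  couplings=np.array([60.0, 45.0]), spacing=1.0)
        th = build_thermal_hamiltonian(dimer_system, bath, 300.0)
        ordering = default_site_ordering(th)
        levels = np.full(th.n_coordinates, 6)
        op = hamiltonian_to_tt_operator(th, ordering, levels)
        state0 = vacuum_product_state(ordering, levels, 2, 0)

        def run(dt):
            cfg = PropagationConfig(dt=dt, t_final=100.0, max_rank=3,
                                    observable_stride=int(round(10.0 / dt)),
                                    krylov_dim=30, krylov_tol=1e-12)
            return propagate(state0, op, cfg, ordering).populations

        ref = run(0.3125)
        e1 = np.max(np.abs(run(2.5) - ref))
        e2 = np.max(np.abs(run(1.25) - ref))
        assert 2.5 < e1 / e2 < 6.5

    def test_norm_and_energy_conservation(self, dimer_tt_setup):
        th, ordering, levels, op, state0 = dimer_tt_setup
        cfg = PropagationConfig(dt=1.0, t_final=200.0, max_rank=8, observable_stride=20)
        traj = propagate(state0, op, cfg, ordering)
        assert np.max(np.abs(traj.norm - 1.0)) < 1e-8
        scale = max(1.0, np.abs(traj.energy[0]))
        assert np.max(np.abs(traj.energy - traj.energy[0])) / scale < 1e-6

    def test_population_sum_is_unity(self, dimer_tt_setup):
        _, ordering, _, op, state0 = dimer_tt_setup
        cfg = PropagationConfig(dt=2.0, t_final=100.0, max_rank=4, observable_stride=10)
        traj = propagate(state0, op, cfg, ordering)
        np.testing.assert_allclose(traj.populations.sum(axis=1), 1.0, atol=1e-6)

    def test_unnormalized_initial_state_rejected(self, dimer_tt_setup):
        _, ordering, levels, op, state0 = dimer_tt_setup
        bad = state0.copy()
        bad.cores[0] = 2.0 * bad.cores[0]
        cfg = PropagationConfig(dt=1.0, t_final=10.0, max_rank=4)
        with pytest.raises(ValueError, match="normalized"):
            propagate(bad, op, cfg, ordering)


class TestKrylov:
    def test_lanczos_matches_dense_expm(self, rng):
        n = 60
        a = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        a = 0.5 * (a + a.conj().T)
        v = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        import scipy.linalg

        z = -0.05j
        exact = scipy.linalg.expm(z * a) @ v
        approx = _lanczos_expm(lambda x: a @ x, v, z, krylov_dim=40, tol=1e-12)
        np.testing.assert_allclose(approx, exact, atol=1e-9)

    def test_nonconvergence_raises_with_diagnostic(self, rng):
        n = 200
        a = np.diag(rng.uniform(0.0, 5000.0, n))
        v = rng.standard_normal(n) + 0j
        with pytest.raises(KrylovConvergenceError, match="did not converge"):
            _lanczos_expm(lambda x: a @ x, v, -1j, krylov_dim=4, tol=1e-14)


class TestRankScan:
    def test_electronic_only_exact_at_any_rank(self, dimer_system):
        _, ordering, op = _electronic_op(
            build_exciton_system([0.0, 100.0], [[0.0, 50.0], [50.0, 0.0]]))
        state = tt_product_state([np.array([1.0, 0.0])])
        cfg = PropagationConfig(dt=1.0, t_final=50.0, max_rank=1, observable_stride=10)
        report = rank_convergence_scan(state, op, cfg, [1, 4], ordering)
        assert report.max_population_diffs[0] < 1e-10
        assert report.converged(1e-8)

    def test_scan_reaches_dense_reference_and_orders_errors(self, dimer_system):
        """Rank-4 run on a 2-mode dimer matches the dense oracle; the scan
        difference reflects the low-rank truncation error."""
        bath = BathDiscretization(frequencies=np.array([150.0]),
                                  couplings=np.array([70.0]), spacing=1.0)
        th = build_thermal_hamiltonian(dimer_system, [bath, bath], 0.0,
                                       tilde_prune_threshold=1e-3)
        ordering = default_site_ordering(th)
        nb = 6
        levels = np.full(th.n_coordinates, nb)
        op = hamiltonian_to_tt_operator(th, ordering, levels)
        state0 = vacuum_product_state(ordering, levels, 2, 0)
        cfg = PropagationConfig(dt=1.0, t_final=100.0, max_rank=2,
                                observable_stride=10, krylov_tol=1e-12)
        report = rank_convergence_scan(state0, op, cfg, [1, 2, 6], ordering)
        p_ref = dense_tfd_populations(th, report.trajectories[-1].times, nb)
        assert np.max(np.abs(report.trajectories[-1].populations - p_ref)) < 1e-8
        # inter-rank differences shrink as rank grows
        assert report.max_population_diffs[1] < report.max_population_diffs[0]

    def test_rejects_non_ascending_ranks(self, dimer_tt_setup):
        _, ordering, _, op, state0 = dimer_tt_setup
        cfg = PropagationConfig(dt=1.0, t_final=10.0, max_rank=2)
        with pytest.raises(ValueError):
            rank_convergence_scan(state0, op, cfg, [4, 2], ordering)
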