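import numpy as np
import pytest
from hypothesis import given, strategies as st

from tfdtt import (
    build_exciton_system,
    build_thermal_hamiltonian,
    default_boson_levels,
    default_site_ordering,
    densify,
    hamiltonian_to_tt_operator,
    inner_product,
    load_tensor_train,
    orthogonalize,
    pad_ranks,
    save_tensor_train,
    tt_norm,
    tt_product_state,
    truncate,
)
from tfdtt.exact_oracle import dense_thermal_hamiltonian
from tfdtt.tensor_train import (
    SiteOrdering,
    apply_tt_operator,
    operator_expectation,
    tt_from_dense,
    vacuum_product_state,
)



class TestProductStates:
    def test_unit_entry_tensor(self):
        tt = tt_product_state([np.array([1.0, 0.0])] * 3)
        dense = densify(tt)
        expected = np.zeros((2, 2, 2))
        expected[0, 0, 0] = 1.0
        np.testing.assert_allclose(dense, expected, atol=1e-15)
        assert tt.ranks == (1, 1)

    def test_densify_matches_outer_product(self, rng):
        vecs = [rng.standard_normal(n) + 1j * rng.standard_normal(n) for n in (2, 3, 4)]
        tt = tt_product_state(vecs)
        expected = np.einsum(
            "i,j,k->ijk", *[v / np.linalg.norm(v) for v in vecs]
        )
        np.testing.assert_allclose(densify(tt), expected, atol=1e-14)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            tt_product_state([np.array([1.0, 0.0]), np.zeros(3)])


class TestOrthogonalization:
    @pytest.mark.parametrize("center", [0, 2, 4])
    def test_densification_preserved_and_isometries(self, rng, center, random_tt):
        tt = random_tt(rng, dims=(2, 3, 2, 3, 2), ranks=(3, 3, 3, 3))
        dense = densify(tt)
        ortho = orthogonalize(tt, center)
        np.testing.assert_allclose(densify(ortho), dense, atol=1e-12)
        for k in range(center):
            c = ortho.cores[k]
            m = c.reshape(-1, c.shape[2])
            np.testing.assert_allclose(m.conj().T @ m, np.eye(c.shape[2]), atol=1e-12)
        for k in range(len(ortho.cores) - 1, center, -1):
            c = ortho.cores[k]
            m = c.reshape(c.shape[0], -1)
            np.testing.assert_allclose(m @ m.conj().T, np.eye(c.shape[0]), atol=1e-12)

    def test_norm_at_center_equals_dense_norm(self, rng, random_tt):
        tt = random_tt(rng, dims=(2, 4, 3), ranks=(2, 3))
        ortho = orthogonalize(tt, 1)
        assert tt_norm(ortho) == pytest.approx(np.linalg.norm(densify(tt)), rel=1e-10)


class TestInnerProduct:
    def test_normalized_and_orthogonal_product_states(self):
        e0 = tt_product_state([np.array([1.0, 0.0]), np.array([1.0, 0.0, 0.0])])
        e1 = tt_product_state([np.array([0.0, 1.0]), np.array([1.0, 0.0, 0.0])])
        assert inner_product(e0, e0) == pytest.approx(1.0, abs=1e-14)
        assert inner_product(e0, e1) == pytest.approx(0.0, abs=1e-14)

    def test_matches_dense_contraction(self, rng, random_tt):
        a = random_tt(rng, dims=(2, 3, 2), ranks=(2, 2))
        b = random_tt(rng, dims=(2, 3, 2), ranks=(3, 2))
        expected = np.vdot(densify(a), densify(b))
        assert inner_product(a, b) == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch_rejected(self, rng, random_tt):
        a = random_tt(rng, dims=(2, 3), ranks=(2,))
        b = random_tt(rng, dims=(2, 4), ranks=(2,))
        with pytest.raises(ValueError):
            inner_product(a, b)


class TestTruncation:
    def test_truncate_to_current_ranks_is_identity(self, rng, random_tt):
        tt = random_tt(rng, dims=(2, 3, 3, 2), ranks=(2, 3, 2))
        out = truncate(tt, max_rank=3)
        np.testing.assert_allclose(densify(out), densify(tt), atol=1e-13)

    def test_rank_one_truncation_of_product_state_is_exact(self):
        tt = tt_product_state([np.array([0.6, 0.8]), np.array([1.0, 1.0]) / np.sqrt(2)])
        out = truncate(tt, max_rank=1)
        np.testing.assert_allclose(densify(out), densify(tt), atol=1e-14)

    def test_error_within_svd_quasi_optimality_bound(self, rng, random_tt):
        """Truncation error <= sqrt(sum over bonds of discarded sv^2) of the
        dense unfoldings (dense SVD oracle)."""
        tt = random_tt(rng, dims=(3, 3, 3, 3), ranks=(4, 6, 4))
        dense = densify(tt)
        r = 2
        bound_sq = 0.0
        for bond in range(1, 4):
            mat = dense.reshape(int(np.prod(dense.shape[:bond])), -1)
            s = np.linalg.svd(mat, compute_uv=False)
            bound_sq += float(np.sum(s[r:] ** 2))
        out = truncate(tt, max_rank=r)
        err = np.linalg.norm(densify(out) - dense)
        assert err <= np.sqrt(bound_sq) + 1e-12
        assert all(rk <= r for rk in out.ranks)


class TestPaddingAndStorage:
    def test_pad_ranks_preserves_state_to_noise_level(self, rng):
        tt = tt_product_state([np.array([1.0, 0.0]), np.array([1.0, 0, 0]), np.array([1.0, 0])])
        padded = pad_ranks(tt, max_rank=2, noise=1e-10)
        assert all(r == 2 for r in padded.ranks)
        assert np.linalg.norm(densify(padded) - densify(tt)) < 1e-8

    def test_storage_scales_as_d_n_r_squared(self, rng, random_tt):
        d, n, r = 8, 3, 4
        tt = random_tt(rng, dims=(n,) * d, ranks=(r,) * (d - 1))
        assert tt.storage_size() == (d - 2) * n * r * r + 2 * n * r


class TestSiteOrderingAndMPO:
    def test_default_ordering_interleaves_tilde_partners(self, dimer_system):
        import numpy as np
        from tfdtt import BathDiscretization

        bath = BathDiscretization(
            frequencies=np.array([120.0, 220.0]),
            couplings=np.array([40.0, 30.0]), spacing=1.0)
        th = build_thermal_hamiltonian(dimer_system, bath, 300.0)
        ordering = default_site_ordering(th)
        assert ordering.positions[0] == "el"
        coords = [th.coordinates[p] for p in ordering.positions[1:]]
        # ascending frequency per site, tilde right after its physical partner
        for a, b in zip(coords[::2], coords[1::2]):
            assert a.site == b.site and a.omega == b.omega
            assert not a.is_tilde and b.is_tilde

    def test_ordering_validation(self):
        with pytest.raises(ValueError):
            SiteOrdering(("el", 0, 0))
        with pytest.raises(ValueError):
            SiteOrdering((0, 1))

    def test_mpo_densify_matches_dense_kron_oracle(self, dimer_thermal_300):
        levels = np.full(dimer_thermal_300.n_coordinates, 4)
        ordering = default_site_ordering(dimer_thermal_300)
        op = hamiltonian_to_tt_operator(dimer_thermal_300, ordering, levels)
        dm = dense_thermal_hamiltonian(dimer_thermal_300, 4)
        np.testing.assert_allclose(op.densify(), dm.hamiltonian, atol=1e-10)
        h = op.densify()
        np.testing.assert_allclose(h, h.conj().T, atol=1e-10)

    def test_mpo_rank_constant_in_chain_length(self, dimer_system):
        from tfdtt import DrudeLorentzDensity, discretize_spectral_density

        sd = DrudeLorentzDensity(35.0, 100.0)
        ranks = []
        for n_modes in (4, 8, 16):
            bath = discretize_spectral_density(sd, n_modes, 2.0, 300.0)
            th = build_thermal_hamiltonian(dimer_system, bath, 300.0)
            op = hamiltonian_to_tt_operator(
                th, default_site_ordering(th), np.full(th.n_coordinates, 3))
            ranks.append(max(w.shape[3] for w in op.op_cores))
        assert ranks[0] == ranks[1] == ranks[2] == dimer_system.n_sites + 2

    def test_t0_tilde_blocks_are_free(self, dimer_system, dimer_baths):
        """At T = 0 the densified operator never changes a tilde occupation."""
        th = build_thermal_hamiltonian(dimer_system, dimer_baths, 0.0)
        nb = 3
        ordering = default_site_ordering(th)
        op = hamiltonian_to_tt_operator(th, ordering, np.full(th.n_coordinates, nb))
        # chain: el, physical, tilde
        h = op.densify().reshape(2, nb, nb, 2, nb, nb)
        for ti in range(nb):
            for tj in range(nb):
                if ti != tj:
                    assert np.abs(h[:, :, ti, :, :, tj]).max() == 0.0

    def test_electronic_only_system(self, dimer_system):
        th = build_thermal_hamiltonian(dimer_system, None, 300.0)
        ordering = default_site_ordering(th)
        op = hamiltonian_to_tt_operator(th, ordering, np.zeros(0, dtype=int))
        np.testing.assert_allclose(op.densify(), dimer_system.electronic_matrix(), atol=1e-12)

    def test_boson_levels_policy(self, dimer_thermal_300):
        levels = default_boson_levels(dimer_thermal_300)
        assert np.all(levels >= 4)
        capped = default_boson_levels(dimer_thermal_300, n_max=5)
        assert np.all(capped <= 5)
        with pytest.raises(ValueError):
            hamiltonian_to_tt_operator(
                dimer_thermal_300, default_site_ordering(dimer_thermal_300),
                np.full(dimer_thermal_300.n_coordinates, 1))


class TestOperatorApplication:
    def test_apply_matches_dense_matvec(self, dimer_thermal_300, rng, random_tt):
        levels = np.full(dimer_thermal_300.n_coordinates, 3)
        ordering = default_site_ordering(dimer_thermal_300)
        op = hamiltonian_to_tt_operator(dimer_thermal_300, ordering, levels)
        tt = random_tt(rng, dims=(2, 3, 3), ranks=(2, 2))
        out = apply_tt_operator(op, tt)
        expected = (op.densify() @ densify(tt).ravel()).reshape(2, 3, 3)
        np.testing.assert_allclose(densify(out), expected, atol=1e-10)

    def test_expectation_matches_dense_sandwich(self, dimer_thermal_300, rng, random_tt):
        levels = np.full(dimer_thermal_300.n_coordinates, 3)
        ordering = default_site_ordering(dimer_thermal_300)
        op = hamiltonian_to_tt_operator(dimer_thermal_300, ordering, levels)
        tt = random_tt(rng, dims=(2, 3, 3), ranks=(2, 2))
        v = densify(tt).ravel()
        expected = np.vdot(v, op.densify() @ v)
        assert operator_expectation(tt, op) == pytest.approx(expected, rel=1e-12)


class TestDenseRoundTrip:
    @given(
        dims=st.lists(st.integers(2, 4), min_size=2, max_size=5),
        seed=st.integers(0, 2**16),
    )
    def test_tt_from_dense_round_trip(self, dims, seed):
        rng = np.random.default_rng(seed)
        tensor = rng.standard_normal(dims) + 1j * rng.standard_normal(dims)
        tt = tt_from_dense(tensor)
        np.testing.assert_allclose(densify(tt), tensor, atol=1e-10)

    def test_serialization_round_trip(self, rng, tmp_path, random_tt):
        tt = random_tt(rng, dims=(2, 3, 4), ranks=(2, 3))
        path = tmp_path / "state.npz"
        save_tensor_train(tt, path)
        back = load_tensor_train(path)
        np.testing.assert_allclose(densify(back), densify(tt), atol=1e-15)

    def test_vacuum_product_state_layout(self, dimer_thermal_300):
        ordering = default_site_ordering(dimer_thermal_300)
        levels = np.full(dimer_thermal_300.n_coordinates, 4)
        tt = vacuum_product_state(ordering, levels, 2, initial_site=1)
        dense = densify(tt)
        assert dense[1, 0, 0] == pytest.approx(1.0)
        assert np.sum(np.abs(dense) > 1e-14) == 1
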