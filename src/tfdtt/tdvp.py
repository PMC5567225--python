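"""Second-order projector-splitting TDVP propagation of a tensor train.

The integrator evolves i d/dt |psi> = H |psi| on the manifold of tensor
trains of fixed rank: a left-to-right sweep of half-step single-core forward
evolutions interleaved with half-step backward evolutions of the bond (rank)
matrices, followed by the mirrored right-to-left sweep.  Each local evolution
uses the effective Hamiltonian obtained by contracting the MPO with the
left/right environments of the orthogonalized state; the matrix exponential
is applied by a Lanczos Krylov method (or densely below a size cutoff).  For
a Hermitian Hamiltonian the scheme preserves norm and energy up to the local
solver tolerance, and it is exact whenever the ranks are full.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from .observables import Trajectory, inverse_participation_ratio, site_populations
from .tensor_train import (
    SiteOrdering,
    TensorTrain,
    TTOperator,
    _qr_left,
    _qr_right,
    operator_expectation,
    orthogonalize,
    pad_ranks,
    tt_norm,
)
from .units import CM1_TO_RAD_FS

__all__ = [
    "PropagationConfig",
    "KrylovConvergenceError",
    "NormDriftError",
    "tdvp_step",
    "propagate",
    "rank_convergence_scan",
    "RankScanReport",
]


class KrylovConvergenceError(RuntimeError):
    pass


class NormDriftError(RuntimeError):
    pass


@dataclass(frozen=True)
class PropagationConfig:
    """Time grid and numerical knobs for a TDVP run.

    dt and t_final are in fs.  ``dense_expm_cutoff`` switches the local
    evolutions to an exact dense matrix exponential when the effective
    problem dimension is at most that size.
    """

    dt: float
    t_final: float
    max_rank: int
    krylov_dim: int = 15
    krylov_tol: float = 1e-10
    observable_stride: int = 1
    dense_expm_cutoff: int = 64
    pad_noise: float = 1e-10
    norm_abort: float = 1e-6

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_final < self.dt:
            raise ValueError("t_final must be >= dt")
        if self.max_rank < 1:
            raise ValueError("max_rank must be >= 1")
        if self.observable_stride < 1:
            raise ValueError("observable_stride must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_final / self.dt))


# ---------------------------------------------------------------------------
# environments and effective operators


def _update_left(env, core, w):
    """Extend a (bra, op, ket) left environment by one site."""
    tmp = np.tensordot(env, core, axes=(2, 0))              # (a, X, t, b')
    tmp = np.tensordot(w, tmp, axes=([0, 2], [1, 2]))       # (s, Y, a, b')
    return np.tensordot(core.conj(), tmp, axes=([0, 1], [2, 0]))  # (b, Y, b')


def _update_right(env, core, w):
    """Extend a (bra, op, ket) right environment by one site."""
    tmp = np.tensordot(core, env, axes=(2, 2))              # (a', t, b, Y)
    tmp = np.tensordot(w, tmp, axes=([2, 3], [1, 3]))       # (X, s, a', b)
    return np.tensordot(core.conj(), tmp, axes=([1, 2], [1, 3]))  # (a, X, a')


def _core_matvec(left, w, right):
    def mv(v3):
        tmp = np.tensordot(left, v3, axes=(2, 0))           # (a, X, t, b')
        tmp = np.tensordot(tmp, w, axes=([1, 2], [0, 2]))   # (a, b', s, Y)
        return np.tensordot(tmp, right, axes=([1, 3], [2, 1]))  # (a, s, b)
    return mv


def _core_dense(left, w, right):
    h = np.einsum("aXc,XstY,bYd->asbctd", left, w, right, optimize=True)
    dim = left.shape[0] * w.shape[1] * right.shape[0]
    return h.reshape(dim, dim)


def _bond_matvec(left, right):
    def mv(s):
        tmp = np.tensordot(left, s, axes=(2, 0))            # (a, X, b')
        return np.tensordot(tmp, right, axes=([1, 2], [1, 2]))  # (a, b)
    return mv


def _bond_dense(left, right):
    h = np.einsum("aXc,bXd->abcd", left, right, optimize=True)
    dim = left.shape[0] * right.shape[0]
    return h.reshape(dim, dim)


def _lanczos_expm(matvec, v, prefactor, krylov_dim, tol):
    """exp(prefactor * A) v for Hermitian A via Lanczos with full reorthogonalization."""
    nrm = np.linalg.norm(v)
    if nrm == 0:
        return v.copy()
    dim = v.size
    m = min(krylov_dim, dim)
    V = np.empty((m + 1, dim), dtype=complex)
    V[0] = v / nrm
    alphas: list[float] = []
    betas: list[float] = []
    for j in range(m):
        w = matvec(V[j])
        alphas.append(float(np.vdot(V[j], w).real))
        w = w - alphas[j] * V[j]
        if j > 0:
            w = w - betas[j - 1] * V[j - 1]
        # full reorthogonalization (cheap at these sizes, essential for tol ~ 1e-12)
        w = w - V[: j + 1].T @ (V[: j + 1].conj() @ w)
        b = float(np.linalg.norm(w))
        t_mat = np.diag(np.asarray(alphas, dtype=float))
        if betas:
            off = np.asarray(betas, dtype=float)
            t_mat += np.diag(off, 1) + np.diag(off, -1)
        y = scipy.linalg.expm(prefactor * t_mat)[:, 0]
        err = abs(b * y[-1]) * abs(prefactor)
        if b < 1e-13 * max(1.0, abs(alphas[j])) or err < tol:
            return nrm * (V[: j + 1].T @ y)
        if j == m - 1:
            if dim <= krylov_dim:
                return nrm * (V[: j + 1].T @ y)
            raise KrylovConvergenceError(
                f"Krylov exponential did not converge: dim={dim}, m={m}, "
                f"estimated error {err:.3e} > tol {tol:.3e}"
            )
        betas.append(b)
        V[j + 1] = w / b
    raise AssertionError("unreachable")


def _local_evolve(left, w, right, tensor, prefactor, cfg: PropagationConfig, bond: bool):
    shape = tensor.shape
    v = tensor.reshape(-1)
    if v.size <= cfg.dense_expm_cutoff:
        h = _bond_dense(left, right) if bond else _core_dense(left, w, right)
        out = scipy.linalg.expm(prefactor * h) @ v
    else:
        mv_t = _bond_matvec(left, right) if bond else _core_matvec(left, w, right)
        mv = lambda x: mv_t(x.reshape(shape)).reshape(-1)
        out = _lanczos_expm(mv, v, prefactor, cfg.krylov_dim, cfg.krylov_tol)
    return out.reshape(shape)


# ---------------------------------------------------------------------------
# the integrator


def tdvp_step(state: TensorTrain, op: TTOperator, dt: float,
              config: PropagationConfig | None = None) -> TensorTrain:
    """One symmetric (second-order) projector-splitting sweep of length dt.

    The state must be gauged with orthogonality center at core 0 (it is
    re-gauged if not); the result is returned in the same gauge.  Ranks are
    unchanged (fixed-rank manifold).
    """
    if config is None:
        config = PropagationConfig(dt=dt, t_final=dt, max_rank=max(state.ranks, default=1))
    if state.orthogonality_center != 0:
        state = orthogonalize(state, 0)
    d = state.n_cores
    W = op.op_cores
    if op.mode_dims != state.mode_dims:
        raise ValueError("operator/state mode dims mismatch")
    cores = [c.copy() for c in state.cores]
    fwd = -1j * (0.5 * dt) * CM1_TO_RAD_FS
    bwd = +1j * (0.5 * dt) * CM1_TO_RAD_FS

    one = np.ones((1, 1, 1), dtype=complex)
    right_envs: list = [None] * (d + 1)
    right_envs[d] = one
    for k in range(d - 1, 0, -1):
        right_envs[k] = _update_right(right_envs[k + 1], cores[k], W[k])

    left_envs: list = [None] * d
    lprev = one
    for k in range(d):
        cores[k] = _local_evolve(lprev, W[k], right_envs[k + 1], cores[k], fwd, config, bond=False)
        if k < d - 1:
            q, r = _qr_left(cores[k])
            cores[k] = q
            lk = _update_left(lprev, q, W[k])
            left_envs[k] = lk
            r = _local_evolve(lk, None, right_envs[k + 1], r, bwd, config, bond=True)
            cores[k + 1] = np.tensordot(r, cores[k + 1], axes=(1, 0))
            lprev = lk

    rnext = one
    for k in range(d - 1, -1, -1):
        lk = left_envs[k - 1] if k > 0 else one
        cores[k] = _local_evolve(lk, W[k], rnext, cores[k], fwd, config, bond=False)
        if k > 0:
            l, q = _qr_right(cores[k])
            cores[k] = q
            rk = _update_right(rnext, q, W[k])
            l = _local_evolve(left_envs[k - 1], None, rk, l, bwd, config, bond=True)
            cores[k - 1] = np.tensordot(cores[k - 1], l, axes=(2, 0))
            rnext = rk
    return TensorTrain(cores, orthogonality_center=0)


def propagate(
    state0: TensorTrain,
    op: TTOperator,
    config: PropagationConfig,
    ordering: SiteOrdering,
    observers: Sequence[Callable[[float, TensorTrain], dict]] | None = None,
) -> Trajectory:
    """Propagate a normalized initial state and sample observables.

    The state is rank-padded to ``config.max_rank`` (deterministic noise of
    relative size ``pad_noise`` seeds the new bond directions), then swept
    with :func:`tdvp_step`.  Every ``observable_stride`` steps the site
    populations, inverse participation ratio, norm and energy (cm^-1) are
    recorded; the run aborts if |norm - 1| exceeds ``norm_abort``.
    """
    nrm = tt_norm(orthogonalize(state0, 0))
    if abs(nrm - 1.0) > 1e-6:
        raise ValueError(f"initial state must be normalized, got norm {nrm}")
    state = pad_ranks(state0, config.max_rank, noise=config.pad_noise)
    state = orthogonalize(state, 0)
    state.cores[0] /= tt_norm(state)

    times, pops, iprs, norms, energies = [], [], [], [], []
    aux: list[dict] = []

    def sample(t: float, st: TensorTrain):
        p = site_populations(st, ordering)
        nn = tt_norm(orthogonalize(st, 0))
        e = operator_expectation(st, op).real
        times.append(t)
        pops.append(p)
        iprs.append(inverse_participation_ratio(np.clip(p, 0.0, None) / max(p.sum(), 1e-300)))
        norms.append(nn)
        energies.append(e)
        if observers:
            aux.append({k: v for obs in observers for k, v in obs(t, st).items()})
        if abs(nn - 1.0) > config.norm_abort:
            raise NormDriftError(
                f"norm drifted to {nn:.12f} at t={t} fs (threshold {config.norm_abort:g}); "
                "reduce dt or raise krylov settings"
            )

    sample(0.0, state)
    for step in range(1, config.n_steps + 1):
        state = tdvp_step(state, op, config.dt, config)
        if step % config.observable_stride == 0 or step == config.n_steps:
            sample(step * config.dt, state)

    traj = Trajectory(
        times=np.asarray(times),
        populations=np.asarray(pops),
        ipr=np.asarray(iprs),
        norm=np.asarray(norms),
        energy=np.asarray(energies),
        aux=aux or None,
    )
    traj.final_state = state
    return traj


@dataclass
class RankScanReport:
    """Convergence-in-rank report: max-over-time population differences
    between consecutive ranks of the same propagation."""

    ranks: list[int]
    max_population_diffs: list[float]
    trajectories: list[Trajectory] = field(default_factory=list)

    def converged(self, tol: float) -> bool:
        return bool(self.max_population_diffs) and self.max_population_diffs[-1] < tol


def rank_convergence_scan(
    state0: TensorTrain,
    op: TTOperator,
    config: PropagationConfig,
    ranks: Sequence[int],
    ordering: SiteOrdering,
    keep_trajectories: bool = True,
) -> RankScanReport:
    """Repeat the same propagation at each max_rank in ascending order and
    report the maximal population difference between consecutive ranks."""
    ranks = list(ranks)
    if len(ranks) < 2 or any(b <= a for a, b in zip(ranks, ranks[1:])):
        raise ValueError("need >= 2 strictly ascending ranks")
    trajs = []
    for r in ranks:
        cfg = PropagationConfig(
            dt=config.dt, t_final=config.t_final, max_rank=r,
            krylov_dim=config.krylov_dim, krylov_tol=config.krylov_tol,
            observable_stride=config.observable_stride,
            dense_expm_cutoff=config.dense_expm_cutoff,
            pad_noise=config.pad_noise, norm_abort=config.norm_abort,
        )
        trajs.append(propagate(state0, op, cfg, ordering))
    diffs = [
        float(np.max(np.abs(a.populations - b.populations)))
        for a, b in zip(trajs, trajs[1:])
    ]
    return RankScanReport(
        ranks=ranks,
        max_population_diffs=diffs,
        trajectories=trajs if keep_trajectories else [],
    )
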