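"""Tensor-train (matrix product state) machinery for the doubled vibronic space.

A state C(i_1,...,i_d) is stored as d order-3 cores G_k of shape
(r_{k-1}, n_k, r_k) with boundary ranks r_0 = r_d = 1, so storage scales as
d*n*r^2 instead of n^d.  Operators are kept in the matching tensor-train
operator (MPO) form with order-4 cores (R_{k-1}, n_k, n_k, R_k).  The
sum-of-products thermal Hamiltonian is converted to an exact MPO by a
finite-state-automaton construction whose bond dimension is set by the number
of distinct electronic projectors that bridge each cut (n_sites + 2 for the
shipped orderings), independent of chain length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .thermofield import ThermalHamiltonian, mixing_angles

__all__ = [
    "TensorTrain",
    "TTOperator",
    "SiteOrdering",
    "tt_product_state",
    "vacuum_product_state",
    "tt_from_dense",
    "densify",
    "orthogonalize",
    "inner_product",
    "tt_norm",
    "truncate",
    "pad_ranks",
    "default_site_ordering",
    "default_boson_levels",
    "hamiltonian_to_tt_operator",
    "operator_expectation",
    "apply_tt_operator",
    "save_tensor_train",
    "load_tensor_train",
]


@dataclass
class TensorTrain:
    """TT/MPS state: cores[k] has shape (r_{k-1}, n_k, r_k)."""

    cores: list[np.ndarray]
    orthogonality_center: int | None = None

    def __post_init__(self):
        if not self.cores:
            raise ValueError("a tensor train needs at least one core")
        if self.cores[0].shape[0] != 1 or self.cores[-1].shape[-1] != 1:
            raise ValueError("boundary ranks must be 1")
        for k in range(len(self.cores) - 1):
            if self.cores[k].shape[2] != self.cores[k + 1].shape[0]:
                raise ValueError(f"rank mismatch between cores {k} and {k + 1}")

    @property
    def n_cores(self) -> int:
        return len(self.cores)

    @property
    def mode_dims(self) -> tuple[int, ...]:
        return tuple(c.shape[1] for c in self.cores)

    @property
    def ranks(self) -> tuple[int, ...]:
        """Internal bond ranks r_1..r_{d-1}."""
        return tuple(c.shape[2] for c in self.cores[:-1])

    def storage_size(self) -> int:
        return sum(c.size for c in self.cores)

    def copy(self) -> "TensorTrain":
        return TensorTrain([c.copy() for c in self.cores], self.orthogonality_center)


@dataclass
class TTOperator:
    """MPO: op_cores[k] has shape (R_{k-1}, n_k, n_k, R_k), boundary ranks 1."""

    op_cores: list[np.ndarray]

    def __post_init__(self):
        if self.op_cores[0].shape[0] != 1 or self.op_cores[-1].shape[-1] != 1:
            raise ValueError("boundary operator ranks must be 1")
        for k in range(len(self.op_cores) - 1):
            if self.op_cores[k].shape[3] != self.op_cores[k + 1].shape[0]:
                raise ValueError(f"operator rank mismatch between cores {k} and {k + 1}")

    @property
    def n_cores(self) -> int:
        return len(self.op_cores)

    @property
    def mode_dims(self) -> tuple[int, ...]:
        return tuple(c.shape[1] for c in self.op_cores)

    def densify(self) -> np.ndarray:
        """Dense matrix over the full product basis (small instances only)."""
        full = int(np.prod(self.mode_dims))
        if full > 4096:
            raise ValueError(f"refusing to densify operator of dimension {full}")
        acc = np.ones((1, 1, 1), dtype=complex)  # (bond, rows, cols)
        for w in self.op_cores:
            tmp = np.einsum("arc,astb->brsct", acc, w, optimize=True)
            acc = tmp.reshape(w.shape[3], acc.shape[1] * w.shape[1], acc.shape[2] * w.shape[2])
        return acc.reshape(acc.shape[1], acc.shape[2])


def tt_product_state(local_states: Sequence[np.ndarray]) -> TensorTrain:
    """Rank-1 TT from normalized local vectors (outer-product state)."""
    cores = []
    for v in local_states:
        v = np.asarray(v, dtype=complex).ravel()
        nrm = np.linalg.norm(v)
        if nrm == 0:
            raise ValueError("zero local vector in product state")
        cores.append((v / nrm).reshape(1, -1, 1))
    return TensorTrain(cores, orthogonality_center=0)


def vacuum_product_state(
    ordering: "SiteOrdering", boson_levels, n_sites: int, initial_site: int = 0
) -> TensorTrain:
    """|initial_site> (x) |0...0>: the rank-1 initial state of a thermal run."""
    levels = np.asarray(boson_levels, dtype=int).ravel()
    locals_ = []
    for p in ordering.positions:
        if p == "el":
            e = np.zeros(n_sites)
            e[initial_site] = 1.0
            locals_.append(e)
        else:
            v = np.zeros(int(levels[p]))
            v[0] = 1.0
            locals_.append(v)
    return tt_product_state(locals_)


def tt_from_dense(tensor: np.ndarray, max_rank: int | None = None, svd_tol: float = 0.0) -> TensorTrain:
    """Sequential-SVD (TT-SVD) decomposition of a dense coefficient tensor."""
    dims = tensor.shape
    d = len(dims)
    cores = []
    mat = np.asarray(tensor, dtype=complex).reshape(dims[0], -1)
    r_prev = 1
    for k in range(d - 1):
        mat = mat.reshape(r_prev * dims[k], -1)
        u, s, vh = np.linalg.svd(mat, full_matrices=False)
        keep = int(np.sum(s > svd_tol)) or 1
        if max_rank is not None:
            keep = min(keep, max_rank)
        cores.append(u[:, :keep].reshape(r_prev, dims[k], keep))
        mat = s[:keep, None] * vh[:keep]
        r_prev = keep
    cores.append(mat.reshape(r_prev, dims[-1], 1))
    return TensorTrain(cores, orthogonality_center=d - 1)


def densify(tt: TensorTrain) -> np.ndarray:
    """Full coefficient tensor of shape mode_dims (small instances only)."""
    if int(np.prod(tt.mode_dims)) > 2_000_000:
        raise ValueError("refusing to densify a large tensor train")
    acc = tt.cores[0].reshape(tt.cores[0].shape[1], tt.cores[0].shape[2])
    for core in tt.cores[1:]:
        acc = np.tensordot(acc, core, axes=(acc.ndim - 1, 0))
    return acc.reshape(tt.mode_dims)


def _qr_left(core: np.ndarray):
    """Left-orthogonal factor: core = Q . R with Q left-isometric."""
    rl, n, rr = core.shape
    q, r = np.linalg.qr(core.reshape(rl * n, rr))
    return q.reshape(rl, n, -1), r


def _qr_right(core: np.ndarray):
    """Right-orthogonal factor: core = L . Q with Q right-isometric."""
    rl, n, rr = core.shape
    qt, rt = np.linalg.qr(core.reshape(rl, n * rr).T)
    return rt.T, qt.T.reshape(-1, n, rr)


def orthogonalize(tt: TensorTrain, center: int) -> TensorTrain:
    """Gauge the TT so cores left of ``center`` are left-isometric and cores
    right of it right-isometric; the densified tensor is unchanged."""
    d = tt.n_cores
    if not 0 <= center < d:
        raise ValueError(f"center {center} out of range for {d} cores")
    cores = [c.astype(complex, copy=True) for c in tt.cores]
    for k in range(center):
        q, r = _qr_left(cores[k])
        cores[k] = q
        cores[k + 1] = np.tensordot(r, cores[k + 1], axes=(1, 0))
    for k in range(d - 1, center, -1):
        l, q = _qr_right(cores[k])
        cores[k] = q
        cores[k - 1] = np.tensordot(cores[k - 1], l, axes=(2, 0))
    return TensorTrain(cores, orthogonality_center=center)


def inner_product(a: TensorTrain, b: TensorTrain) -> complex:
    """<a|b> by transfer-matrix contraction (conjugate-linear in ``a``)."""
    if a.mode_dims != b.mode_dims:
        raise ValueError(f"mode dims mismatch: {a.mode_dims} vs {b.mode_dims}")
    env = np.ones((1, 1), dtype=complex)
    for ca, cb in zip(a.cores, b.cores):
        tmp = np.tensordot(env, cb, axes=(1, 0))          # (ra, n, rb')
        env = np.tensordot(ca.conj(), tmp, axes=([0, 1], [0, 1]))  # (ra', rb')
    return complex(env[0, 0])


def tt_norm(tt: TensorTrain) -> float:
    if tt.orthogonality_center is not None:
        return float(np.linalg.norm(tt.cores[tt.orthogonality_center]))
    return math.sqrt(max(inner_product(tt, tt).real, 0.0))


def truncate(tt: TensorTrain, max_rank: int, svd_tol: float = 0.0) -> TensorTrain:
    """SVD truncation to ranks <= max_rank, dropping singular values <= svd_tol.

    The sweep runs over an orthogonalized copy, so the densification error is
    bounded by sqrt(sum of discarded singular values squared) (quasi-optimal).
    """
    if max_rank < 1:
        raise ValueError("max_rank must be >= 1")
    if svd_tol < 0:
        raise ValueError("svd_tol must be >= 0")
    work = orthogonalize(tt, 0)
    cores = work.cores
    d = len(cores)
    for k in range(d - 1):
        rl, n, rr = cores[k].shape
        u, s, vh = np.linalg.svd(cores[k].reshape(rl * n, rr), full_matrices=False)
        keep = int(np.sum(s > svd_tol))
        keep = max(1, min(keep, max_rank))
        cores[k] = u[:, :keep].reshape(rl, n, keep)
        carry = (s[:keep, None] * vh[:keep])
        cores[k + 1] = np.tensordot(carry, cores[k + 1], axes=(1, 0))
    return TensorTrain(cores, orthogonality_center=d - 1)


def _max_reachable_ranks(dims: Sequence[int]) -> list[int]:
    d = len(dims)
    cap = 1 << 40  # saturate: long chains overflow an exact product
    left, acc = [], 1
    for n in dims:
        acc = min(acc * int(n), cap)
        left.append(acc)
    right = [0] * d
    acc = 1
    for i in range(d - 1, -1, -1):
        acc = min(acc * int(dims[i]), cap)
        right[i] = acc
    return [min(left[k], right[k + 1]) for k in range(d - 1)]


def pad_ranks(tt: TensorTrain, max_rank: int, noise: float = 1e-10, seed: int = 0) -> TensorTrain:
    """Enlarge internal ranks toward ``max_rank`` (capped at the reachable rank).

    New entries are seeded with deterministic noise of relative scale
    ``noise`` so that a fixed-rank integrator can rotate amplitude into the
    enlarged bond directions; ``noise=0`` gives literal zero padding.
    """
    dims = tt.mode_dims
    caps = _max_reachable_ranks(dims)
    targets = [min(max_rank, c) for c in caps]
    rng = np.random.default_rng(seed)
    scale = noise * (tt_norm(tt) / max(1, tt.storage_size())) if noise else 0.0
    cores = []
    d = tt.n_cores
    for k, core in enumerate(tt.cores):
        rl = 1 if k == 0 else targets[k - 1]
        rr = 1 if k == d - 1 else targets[k]
        new = np.zeros((rl, core.shape[1], rr), dtype=complex)
        if scale:
            new[:] = scale * (rng.standard_normal(new.shape) + 1j * rng.standard_normal(new.shape))
        new[: core.shape[0], :, : core.shape[2]] = core
        cores.append(new)
    return TensorTrain(cores, orthogonality_center=None)


# ---------------------------------------------------------------------------
# site ordering and MPO construction


@dataclass(frozen=True)
class SiteOrdering:
    """Chain placement of the electronic core and the boson coordinates.

    ``positions[p]`` is either the string ``"el"`` (electronic core) or the
    integer index of a coordinate in ``ThermalHamiltonian.coordinates``.
    """

    positions: tuple

    def __post_init__(self):
        coords = [p for p in self.positions if p != "el"]
        if self.positions.count("el") != 1:
            raise ValueError("ordering must place the electronic core exactly once")
        if len(set(coords)) != len(coords):
            raise ValueError("ordering repeats a coordinate")

    @property
    def electronic_position(self) -> int:
        return self.positions.index("el")

    @property
    def n_positions(self) -> int:
        return len(self.positions)


def default_site_ordering(thermal: ThermalHamiltonian) -> SiteOrdering:
    """Electronic core first, then per-site mode groups ascending in
    frequency, each tilde coordinate adjacent to its physical partner."""
    by_site: dict[int, dict[int, dict[bool, int]]] = {}
    for idx, c in enumerate(thermal.coordinates):
        by_site.setdefault(c.site, {}).setdefault(c.mode_index, {})[c.is_tilde] = idx
    positions: list = ["el"]
    for site in sorted(by_site):
        modes = by_site[site]

        def _mode_omega(m):
            any_idx = next(iter(modes[m].values()))
            return thermal.coordinates[any_idx].omega

        order = sorted(modes, key=lambda m: (_mode_omega(m), m))
        for m in order:
            if False in modes[m]:
                positions.append(modes[m][False])
            if True in modes[m]:
                positions.append(modes[m][True])
    if len(positions) != thermal.n_coordinates + 1:
        raise AssertionError("ordering lost coordinates")
    return SiteOrdering(tuple(positions))


def default_boson_levels(
    thermal: ThermalHamiltonian,
    c: float = 3.0,
    n_min: int = 4,
    n_max: int | None = None,
) -> np.ndarray:
    """Per-coordinate boson basis sizes: max(n_min, ceil(c*(nbar+1)) + 2).

    nbar is the Bose occupation of the parent mode at the build temperature;
    thermally excited low-frequency modes get more levels.  ``n_max`` caps
    the count for reduced-scale runs.
    """
    levels = []
    for coord in thermal.coordinates:
        tp = mixing_angles([coord.omega], thermal.temperature)
        nbar = float(tp.occupation()[0])
        n = max(n_min, int(math.ceil(c * (nbar + 1.0))) + 2)
        if n_max is not None:
            n = min(n, n_max)
        levels.append(max(n, 2))
    return np.asarray(levels, dtype=int)


def _number_op(n: int) -> np.ndarray:
    return np.diag(np.arange(n, dtype=float))


def _x_op(n: int) -> np.ndarray:
    """a + a^dag on an n-level truncated boson."""
    a = np.diag(np.sqrt(np.arange(1, n, dtype=float)), 1)
    return a + a.T


def hamiltonian_to_tt_operator(
    thermal: ThermalHamiltonian,
    ordering: SiteOrdering,
    boson_levels,
) -> TTOperator:
    """Exact MPO of the thermal Hamiltonian for a given chain ordering.

    The construction is the standard finite-state automaton for a sum of
    one-body terms and (electronic projector) x (boson displacement) two-body
    terms; no compression is applied.
    """
    n_sites = thermal.system.n_sites
    levels = np.asarray(boson_levels, dtype=int).ravel()
    if len(levels) != thermal.n_coordinates:
        raise ValueError("need one boson level count per retained coordinate")
    if np.any(levels < 2):
        raise ValueError("boson truncation levels must be >= 2")
    d = ordering.n_positions
    if d != thermal.n_coordinates + 1:
        raise ValueError("ordering does not cover all coordinates")

    dims = []
    for p in ordering.positions:
        dims.append(n_sites if p == "el" else int(levels[p]))

    el_pos = ordering.electronic_position
    pos_of_coord = {p: i for i, p in enumerate(ordering.positions) if p != "el"}

    # one-body terms: (position, matrix)
    one_body: dict[int, np.ndarray] = {el_pos: thermal.system.electronic_matrix().astype(complex)}
    # two-body terms: (posA, keyA, matA, posB, matB, coeff)
    two_body = []
    for idx, coord in enumerate(thermal.coordinates):
        p = pos_of_coord[idx]
        nb = dims[p]
        one_body[p] = one_body.get(p, np.zeros((nb, nb), dtype=complex)) + coord.signed_omega * _number_op(nb)
        proj = np.zeros((n_sites, n_sites), dtype=complex)
        proj[coord.site, coord.site] = 1.0
        coeff = -coord.coupling / math.sqrt(2.0)
        if coeff == 0.0:
            continue
        if el_pos < p:
            two_body.append((el_pos, ("proj", coord.site), proj, p, _x_op(nb).astype(complex), coeff))
        else:
            two_body.append((p, ("x", idx), _x_op(nb).astype(complex), el_pos, proj, coeff))

    # channel live ranges: a channel occupies bonds posA .. max(posB)-1
    chan_last: dict[tuple, int] = {}
    chan_open: dict[tuple, tuple[int, np.ndarray]] = {}
    for pa, key, ma, pb, _, _ in two_body:
        ck = (pa, key)
        chan_last[ck] = max(chan_last.get(ck, -1), pb - 1)
        chan_open[ck] = (pa, ma)

    def bond_states(bond: int) -> list:
        if bond < 0:
            return ["B"]
        if bond >= d - 1:
            return ["E"]
        states: list = ["E"]
        for ck in sorted(chan_open, key=repr):
            if chan_open[ck][0] <= bond <= chan_last[ck]:
                states.append(ck)
        states.append("B")
        return states

    cores = []
    for k in range(d):
        sin = bond_states(k - 1)
        sout = bond_states(k)
        iin = {s: i for i, s in enumerate(sin)}
        iout = {s: i for i, s in enumerate(sout)}
        n = dims[k]
        eye = np.eye(n, dtype=complex)
        w = np.zeros((len(sin), n, n, len(sout)), dtype=complex)
        if "B" in iin and "B" in iout:
            w[iin["B"], :, :, iout["B"]] = eye
        if "E" in iin and "E" in iout:
            w[iin["E"], :, :, iout["E"]] = eye
        if k in one_body and "B" in iin and "E" in iout:
            w[iin["B"], :, :, iout["E"]] += one_body[k]
        for ck, (pa, ma) in chan_open.items():
            if pa == k and "B" in iin and ck in iout:
                w[iin["B"], :, :, iout[ck]] += ma
            if ck in iin and ck in iout:
                w[iin[ck], :, :, iout[ck]] = eye
        for pa, key, _, pb, mb, coeff in two_body:
            if pb == k:
                ck = (pa, key)
                w[iin[ck], :, :, iout["E"]] += coeff * mb
        cores.append(w)
    return TTOperator(cores)


def apply_tt_operator(op: TTOperator, tt: TensorTrain) -> TensorTrain:
    """Exact MPO-MPS product; output ranks are products R_k * r_k."""
    if op.mode_dims != tt.mode_dims:
        raise ValueError("operator/state mode dims mismatch")
    cores = []
    for w, a in zip(op.op_cores, tt.cores):
        new = np.einsum("XstY,atb->XasYb", w, a, optimize=True)
        R0, r0 = w.shape[0], a.shape[0]
        R1, r1 = w.shape[3], a.shape[2]
        cores.append(new.reshape(R0 * r0, w.shape[1], R1 * r1))
    return TensorTrain(cores, orthogonality_center=None)


def operator_expectation(state: TensorTrain, op: TTOperator, ket: TensorTrain | None = None) -> complex:
    """<state|op|ket> sandwich contraction (ket defaults to state)."""
    if ket is None:
        ket = state
    if op.mode_dims != state.mode_dims or op.mode_dims != ket.mode_dims:
        raise ValueError("operator/state mode dims mismatch")
    env = np.ones((1, 1, 1), dtype=complex)  # (bra rank, op rank, ket rank)
    for ca, w, cb in zip(state.cores, op.op_cores, ket.cores):
        tmp = np.tensordot(env, cb, axes=(2, 0))              # (a, X, t, b')
        tmp = np.tensordot(w, tmp, axes=([0, 2], [1, 2]))     # (s, Y, a, b')
        env = np.tensordot(ca.conj(), tmp, axes=([0, 1], [2, 0]))  # (a', Y, b')
    return complex(env[0, 0, 0])


# ---------------------------------------------------------------------------
# checkpoint serialization (single-archive, version-tagged)

_TT_FORMAT_VERSION = 1


def save_tensor_train(tt: TensorTrain, path) -> None:
    """Save to a .npz archive: version tag, core count, complex cores."""
    payload = {f"core_{k}": c for k, c in enumerate(tt.cores)}
    center = -1 if tt.orthogonality_center is None else tt.orthogonality_center
    np.savez(path, version=_TT_FORMAT_VERSION, n_cores=tt.n_cores, center=center, **payload)


def load_tensor_train(path) -> TensorTrain:
    with np.load(path) as data:
        version = int(data["version"])
        if version != _TT_FORMAT_VERSION:
            raise ValueError(f"unsupported tensor-train archive version {version}")
        n = int(data["n_cores"])
        center = int(data["center"])
        cores = [np.asarray(data[f"core_{k}"], dtype=complex) for k in range(n)]
    return TensorTrain(cores, orthogonality_center=None if center < 0 else center)
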