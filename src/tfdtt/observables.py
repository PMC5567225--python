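"""Site populations, exciton delocalization and generic expectation values.

Populations p_n(t) = <phi|(|n><n| x 1)|phi> need no thermal dressing: the
electronic projector contains no boson operators and therefore commutes with
the Bogoliubov generator.  The inverse participation ratio

    Pi(t) = 1 / sum_n p_n(t)^2

ranges from 1 (exciton fully localized on one site) to n_sites (perfectly
uniform), and measures the effective number of sites the exciton occupies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tensor_train import (
    SiteOrdering,
    TensorTrain,
    TTOperator,
    operator_expectation,
    orthogonalize,
)

__all__ = [
    "Trajectory",
    "site_populations",
    "inverse_participation_ratio",
    "generic_expectation",
    "write_trajectory_tsv",
    "read_trajectory_tsv",
]


@dataclass
class Trajectory:
    """Sampled propagation record: populations are (samples x n_sites)."""

    times: np.ndarray
    populations: np.ndarray
    ipr: np.ndarray
    norm: np.ndarray
    energy: np.ndarray
    aux: list | None = None
    final_state: TensorTrain | None = field(default=None, repr=False)

    @property
    def n_sites(self) -> int:
        return self.populations.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_fs": self.times}
        for n in range(self.n_sites):
            cols[f"p_{n + 1}"] = self.populations[:, n]
        cols["ipr"] = self.ipr
        cols["norm"] = self.norm
        cols["energy_cm1"] = self.energy
        return pd.DataFrame(cols)


def site_populations(state: TensorTrain, ordering: SiteOrdering) -> np.ndarray:
    """Electronic site populations by the orthogonality-center contraction.

    The state is gauged to the electronic core; the diagonal of the reduced
    electronic density matrix is then a single contraction of that core over
    its rank indices.  Equals the projector expectation value but needs no
    operator build.
    """
    pos = ordering.electronic_position
    st = orthogonalize(state, pos)
    core = st.cores[pos]
    p = np.einsum("anb,anb->n", core.conj(), core).real
    return p


def inverse_participation_ratio(p) -> float:
    """Pi = 1 / sum_n p_n^2 for a population vector summing to ~1."""
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0 or np.all(p == 0):
        raise ValueError("population vector must be nonzero")
    if np.any(p < -1e-9):
        raise ValueError("populations must be nonnegative")
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"populations must sum to 1 within 1e-6, got {total}")
    return float(1.0 / np.sum(p**2))


def generic_expectation(state: TensorTrain, op: TTOperator) -> complex:
    """<phi|A_theta|phi> for an operator already in MPO form."""
    return operator_expectation(state, op)


def write_trajectory_tsv(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_trajectory_tsv(path) -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    pcols = [c for c in df.columns if c.startswith("p_")]
    return Trajectory(
        times=df["time_fs"].to_numpy(),
        populations=df[pcols].to_numpy(),
        ipr=df["ipr"].to_numpy(),
        norm=df["norm"].to_numpy(),
        energy=df["energy_cm1"].to_numpy(),
    )
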