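"""Random adjacency construction for the two-area cortical network.

Each area holds N_E pyramidal cells followed by N_I interneurons (the first
N_E indices are excitatory — a documented convention carried through all
modules).  Adjacency matrices are binary with rows indexing the *receiving*
neuron: eps[i, j] = 1 iff j is presynaptic to i, matching the summation over
presynaptic neurons in the synaptic-current equations.  Self-connections are
excluded.

Within an area, every potential edge j -> i exists independently with the
receiver's reception probability: p_E_rec for pyramidal receivers (5% in the
sensory area, 20% in the association area) and a fixed 20% for interneuron
receivers.  Across areas only pyramidal cells project.  The feedforward
projection (sensory -> association) targets association pyramidal cells only
(reception probability 20%); the feedback projection (association -> sensory)
is diffuse, targeting sensory pyramidal cells and interneurons at 5% each.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AreaSpec",
    "AdjacencyPair",
    "SENSORY",
    "ASSOCIATION",
    "build_intra",
    "build_inter",
    "build_network",
    "save_dense",
    "load_dense",
    "save_edge_list",
    "load_edge_list",
]


@dataclass(frozen=True)
class AreaSpec:
    """One cortical area: population sizes and reception probabilities."""

    name: str
    N_E: int = 80
    N_I: int = 20
    p_E_rec: float = 0.20     # intra-area reception probability of pyramidal cells
    p_I_rec: float = 0.20     # intra-area reception probability of interneurons
    p_E_ext: float = 0.20     # cross-area reception probability of pyramidal cells
    p_I_ext: float = 0.05     # cross-area reception probability of interneurons

    def __post_init__(self) -> None:
        if self.N_E <= 0 or self.N_I <= 0:
            raise ValueError("population sizes must be positive")
        for name in ("p_E_rec", "p_I_rec", "p_E_ext", "p_I_ext"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def N(self) -> int:
        return self.N_E + self.N_I

    def labels(self) -> np.ndarray:
        """Boolean node labels, True = excitatory (first N_E indices)."""
        return np.arange(self.N) < self.N_E


SENSORY = AreaSpec("sensory", p_E_rec=0.05, p_E_ext=0.05)
ASSOCIATION = AreaSpec("association", p_E_rec=0.20, p_E_ext=0.20)


@dataclass
class AdjacencyPair:
    """Recurrent matrices of both areas plus the two cross-area projections.

    All matrices are binary with row = receiver.  ``ff`` is the feedforward
    (sensory E -> association) matrix of shape (N_assoc, N_sens); ``fb`` the
    feedback (association E -> sensory) matrix of shape (N_sens, N_assoc).
    """

    sensory: AreaSpec
    association: AreaSpec
    M_rec_sens: np.ndarray
    M_rec_assoc: np.ndarray
    ff: np.ndarray
    fb: np.ndarray


def _check_seed(seed) -> None:
    if seed is None:
        raise ValueError("a seed is required for reproducible construction")


def build_intra(area: AreaSpec, seed: int) -> np.ndarray:
    """Recurrent adjacency of one area; reproducible given the seed."""
    _check_seed(seed)
    rng = np.random.default_rng(seed)
    p_row = np.where(area.labels(), area.p_E_rec, area.p_I_rec)
    M = (rng.random((area.N, area.N)) < p_row[:, None]).astype(np.int8)
    np.fill_diagonal(M, 0)
    return M


def build_inter(source: AreaSpec, target: AreaSpec, direction: str,
                seed: int) -> np.ndarray:
    """Cross-area adjacency (rows: target neurons, cols: source neurons).

    Only pyramidal cells project across areas, so all columns of interneuron
    sources are zero.  Feedforward targets pyramidal cells only; feedback
    targets both classes of the sensory area.
    """
    _check_seed(seed)
    if direction == "feedforward":
        if not (source.name == "sensory" and target.name == "association"):
            raise ValueError("feedforward runs sensory -> association")
    elif direction == "feedback":
        if not (source.name == "association" and target.name == "sensory"):
            raise ValueError("feedback runs association -> sensory")
    else:
        raise ValueError(f"unknown direction {direction!r}")
    rng = np.random.default_rng(seed)
    if direction == "feedforward":
        p_row = np.where(target.labels(), target.p_E_ext, 0.0)
    else:
        p_row = np.where(target.labels(), target.p_E_ext, target.p_I_ext)
    M = (rng.random((target.N, source.N)) < p_row[:, None]).astype(np.int8)
    M[:, ~source.labels()] = 0          # interneurons never project across areas
    return M


def build_network(sensory: AreaSpec = SENSORY,
                  association: AreaSpec = ASSOCIATION,
                  seed: int = 0) -> AdjacencyPair:
    """Build the full two-area network from one topology seed."""
    _check_seed(seed)
    ss = np.random.SeedSequence(seed).spawn(4)
    child = [int(s.generate_state(1)[0]) for s in ss]
    return AdjacencyPair(
        sensory=sensory,
        association=association,
        M_rec_sens=build_intra(sensory, child[0]),
        M_rec_assoc=build_intra(association, child[1]),
        ff=build_inter(sensory, association, "feedforward", child[2]),
        fb=build_inter(association, sensory, "feedback", child[3]),
    )


# ---------------------------------------------------------------------------
# file I/O: dense whitespace-delimited matrices and 3-column edge lists
# ---------------------------------------------------------------------------

def save_dense(path, M: np.ndarray) -> None:
    np.savetxt(path, np.asarray(M, dtype=int), fmt="%d")


def load_dense(path) -> np.ndarray:
    M = np.loadtxt(path, dtype=int)
    if M.ndim == 1:                     # single-row matrix
        M = M[None, :]
    return M.astype(np.int8)


def save_edge_list(path, M: np.ndarray, tag: str = "rec") -> None:
    """Three-column edge list: presynaptic, postsynaptic, tag."""
    post, pre = np.nonzero(np.asarray(M))
    pd.DataFrame({"pre": pre, "post": post, "tag": tag}).to_csv(path, index=False)


def load_edge_list(path, shape=None) -> np.ndarray:
    df = pd.read_csv(path)
    if shape is None:
        n = int(max(df["pre"].max(), df["post"].max())) + 1
        shape = (n, n)
    M = np.zeros(shape, dtype=np.int8)
    M[df["post"].to_numpy(), df["pre"].to_numpy()] = 1
    return M
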