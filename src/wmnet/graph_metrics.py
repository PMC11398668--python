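"""Structural metrics of the recurrent cortical graph.

All metrics operate on a binary adjacency matrix M with rows indexing the
receiving neuron (M[i, j] = 1 iff j -> i) and a boolean label vector marking
excitatory nodes.  Three views recur throughout: the entire network, the
excitatory subnetwork (subgraph induced by pyramidal cells), and the
inhibitory-involved remainder (entire minus excitatory, class-wise).

The seventeen structural variables collected by :func:`feature_vector`:

======== =====================================================================
d_EtoE..  edge counts of the four source->target class blocks
F_EI      E/I balance factor (d_EtoE + d_ItoI) / (d_EtoI + d_ItoE)
P_E_hub   fraction of pyramidal cells whose excitatory-input share P_i > 0.8
P_I_hub   same fraction over interneurons
F_richhub P_E_hub / P_I_hub
C3_E      directed 3-cycles in the excitatory subnetwork
C3_inh    inhibitory-involved 3-cycles (entire - excitatory)
F_cycle   C3_E / C3_inh
Cc_all/E  average clustering coefficient (undirected projection), both views
R_Cc      Cc_E / Cc_all
L_all/E   average shortest path length over reachable ordered pairs
R_L       L_E / L_all
======== =====================================================================

Undefined quantities (zero denominators, no reachable pairs) are returned as
NaN rather than raised, so ensemble tables can carry missing entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "FEATURE_NAMES",
    "MOTIF_NAMES",
    "MotifCensus",
    "avg_shortest_path",
    "avg_clustering",
    "degree_blocks",
    "ei_balance_factor",
    "excitatory_input_fraction",
    "hub_measures",
    "count_3cycles",
    "count_4cycles",
    "motif_census",
    "feature_vector",
]

FEATURE_NAMES = (
    "d_EtoE", "d_EtoI", "d_ItoE", "d_ItoI", "F_EI",
    "P_E_hub", "P_I_hub", "F_richhub",
    "C3_E", "C3_inh", "F_cycle",
    "Cc_all", "Cc_E", "R_Cc",
    "L_all", "L_E", "R_L",
)

HUB_THRESHOLD = 0.80


def _as_binary(M) -> np.ndarray:
    M = np.asarray(M)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if not np.isin(M, (0, 1)).all():
        raise ValueError("adjacency matrix must be binary")
    return M.astype(np.int64)


def _labels(M: np.ndarray, labels) -> np.ndarray:
    lab = np.asarray(labels, dtype=bool)
    if lab.shape[0] != M.shape[0]:
        raise ValueError("label length does not match matrix size")
    return lab


# ---------------------------------------------------------------------------
# small-world ingredients
# ---------------------------------------------------------------------------

def avg_shortest_path(M, with_counts: bool = False):
    """Mean directed shortest-path length over reachable ordered pairs.

    Unreachable pairs are excluded; their count is reported when
    ``with_counts`` is set.  NaN when no ordered pair is reachable.
    """
    M = _as_binary(M)
    n = M.shape[0]
    # row = receiver, so path lengths along edge direction run on M.T
    D = shortest_path(np.asarray(M.T, dtype=float), method="D", unweighted=True)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    n_unreachable = int(off.sum() - finite.sum())
    mean = float(D[finite].mean()) if finite.any() else float("nan")
    if with_counts:
        return mean, n_unreachable
    return mean


def avg_clustering(M) -> float:
    """Average local clustering coefficient on the undirected projection.

    Cc_i = 2 E_i / (k_i (k_i - 1)) with E_i the number of edges among the
    neighbors of i; nodes with k_i < 2 contribute 0.
    """
    M = _as_binary(M)
    A = ((M + M.T) > 0).astype(np.int64)
    np.fill_diagonal(A, 0)
    k = A.sum(axis=1)
    closed = np.diag(A @ A @ A)                 # 2 E_i: each triangle at i twice
    denom = k * (k - 1)
    cc = np.divide(closed, denom, out=np.zeros(M.shape[0], dtype=float),
                   where=denom > 0)
    return float(cc.mean())


# ---------------------------------------------------------------------------
# E/I composition
# ---------------------------------------------------------------------------

def degree_blocks(M, labels) -> tuple[int, int, int, int]:
    """Edge counts (d_EtoE, d_EtoI, d_ItoE, d_ItoI), source class -> target class."""
    M = _as_binary(M)
    lab = _labels(M, labels)
    E, I = lab, ~lab
    d_EtoE = int(M[np.ix_(E, E)].sum())
    d_EtoI = int(M[np.ix_(I, E)].sum())     # rows = receivers (I), cols = sources (E)
    d_ItoE = int(M[np.ix_(E, I)].sum())
    d_ItoI = int(M[np.ix_(I, I)].sum())
    return d_EtoE, d_EtoI, d_ItoE, d_ItoI


def ei_balance_factor(blocks) -> float:
    """(d_EtoE + d_ItoI) / (d_EtoI + d_ItoE); NaN for a zero denominator."""
    d_EtoE, d_EtoI, d_ItoE, d_ItoI = blocks
    denom = d_EtoI + d_ItoE
    if denom == 0:
        return float("nan")
    return (d_EtoE + d_ItoI) / denom


def excitatory_input_fraction(M, labels) -> np.ndarray:
    """Per-node excitatory share of inputs P_i = k_i^E / (k_i^E + k_i^I).

    NaN for nodes without any input.
    """
    M = _as_binary(M)
    lab = _labels(M, labels)
    k_E = M[:, lab].sum(axis=1).astype(float)
    k_I = M[:, ~lab].sum(axis=1).astype(float)
    tot = k_E + k_I
    return np.divide(k_E, tot, out=np.full(M.shape[0], np.nan), where=tot > 0)


def hub_measures(P, labels, threshold: float = HUB_THRESHOLD):
    """Hub fractions per class and their ratio.

    A node is a hub when its excitatory-input share strictly exceeds the
    threshold; P_E_hub (P_I_hub) is the hub fraction among pyramidal cells
    (interneurons).  F_richhub = P_E_hub / P_I_hub, NaN when P_I_hub = 0.
    """
    P = np.asarray(P, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if P.shape[0] != lab.shape[0]:
        raise ValueError("label length does not match P")
    is_hub = P > threshold                   # NaN compares False: no input, no hub
    p_e = float(is_hub[lab].mean()) if lab.any() else float("nan")
    p_i = float(is_hub[~lab].mean()) if (~lab).any() else float("nan")
    f = p_e / p_i if p_i and not np.isnan(p_i) else float("nan")
    return p_e, p_i, f


# ---------------------------------------------------------------------------
# cycles
# ---------------------------------------------------------------------------

def count_3cycles(M, view: str = "entire", labels=None) -> int:
    """Number of directed 3-cycles, trace(M^3)/3, on the requested view."""
    M = _as_binary(M)
    if view == "excitatory":
        lab = _labels(M, labels)
        M = M[np.ix_(lab, lab)]
    elif view != "entire":
        raise ValueError("view must be 'entire' or 'excitatory'")
    return int(round(np.trace(M @ M @ M) / 3))


def count_4cycles(M) -> int:
    """Number of simple directed 4-cycles.

    trace(M^4) counts closed 4-walks; the degenerate ones bounce through
    mutual dyads (i->j->i->k->i and i->j->k->j->i, including j = k) and are
    subtracted: C4 = (trace(M^4) - sum_i (2 b_i^2 - b_i)) / 4 with b_i the
    number of mutual partners of node i.
    """
    M = _as_binary(M)
    B = M * M.T
    b = B.sum(axis=1)
    tr4 = np.trace(np.linalg.matrix_power(M, 4))
    return int(round((tr4 - np.sum(2 * b ** 2 - b)) / 4))


# ---------------------------------------------------------------------------
# triad motifs
# ---------------------------------------------------------------------------

#: the 13 connected 3-node digraph classes, ordered by the standard
#: triad-significance-profile convention: 1-3 two edges, 4-7 three edges,
#: 8-11 four edges, 12 five edges, 13 six edges.
MOTIF_NAMES = ("021D", "021U", "021C", "111D", "111U", "030T", "030C",
               "120D", "120U", "120C", "201", "210", "300")

#: exemplar edge lists (source -> target) on nodes {0, 1, 2}
_MOTIF_EXEMPLARS = {
    "021D": [(0, 1), (0, 2)],
    "021U": [(1, 0), (2, 0)],
    "021C": [(0, 1), (1, 2)],
    "111D": [(0, 1), (1, 0), (2, 0)],
    "111U": [(0, 1), (1, 0), (0, 2)],
    "030T": [(0, 1), (0, 2), (1, 2)],
    "030C": [(0, 1), (1, 2), (2, 0)],
    "120D": [(0, 1), (1, 0), (2, 0), (2, 1)],
    "120U": [(0, 1), (1, 0), (0, 2), (1, 2)],
    "120C": [(0, 1), (1, 0), (1, 2), (2, 0)],
    "201": [(0, 1), (1, 0), (0, 2), (2, 0)],
    "210": [(0, 1), (1, 0), (1, 2), (2, 1), (0, 2)],
    "300": [(0, 1), (1, 0), (1, 2), (2, 1), (0, 2), (2, 0)],
}


def _edge_code(pairs) -> int:
    """6-bit code of a 3-node digraph: bits (0>1, 1>0, 0>2, 2>0, 1>2, 2>1)."""
    bit = {(0, 1): 0, (1, 0): 1, (0, 2): 2, (2, 0): 3, (1, 2): 4, (2, 1): 5}
    code = 0
    for e in pairs:
        code |= 1 << bit[e]
    return code


def _permute_code(code: int, perm) -> int:
    pairs = []
    bit = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
    for b, (a, c) in enumerate(bit):
        if code >> b & 1:
            pairs.append((perm[a], perm[c]))
    return _edge_code(pairs)


def _build_code_table() -> np.ndarray:
    """Map each of the 64 edge codes to a motif class (1..13) or 0."""
    canon_to_class: dict[int, int] = {}
    for cls, name in enumerate(MOTIF_NAMES, start=1):
        code = _edge_code(_MOTIF_EXEMPLARS[name])
        canon = min(_permute_code(code, p) for p in permutations(range(3)))
        canon_to_class[canon] = cls
    table = np.zeros(64, dtype=np.int64)
    for code in range(64):
        canon = min(_permute_code(code, p) for p in permutations(range(3)))
        table[code] = canon_to_class.get(canon, 0)
    # the only unclassified codes are the weakly disconnected ones: the empty
    # graph (1), a single edge (6) or a single mutual dyad (3)
    assert int((table == 0).sum()) == 10
    return table


_CODE_TABLE = _build_code_table()


@dataclass
class MotifCensus:
    """Counts of the 13 connected triad classes on the three views."""

    entire: np.ndarray
    excitatory: np.ndarray
    inhibitory_involved: np.ndarray
    F_motifs: np.ndarray          # excitatory / inhibitory-involved, per class

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"entire": self.entire, "excitatory": self.excitatory,
             "inhibitory_involved": self.inhibitory_involved,
             "F_motifs": self.F_motifs},
            index=pd.Index(range(1, 14), name="motif"))


def _census_counts(M: np.ndarray) -> np.ndarray:
    n = M.shape[0]
    counts = np.zeros(13, dtype=np.int64)
    # only triples around at least one edge can be connected
    A = ((M + M.T) > 0)
    neighbors = [np.flatnonzero(A[i]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                code = (int(M[j, i]) | int(M[i, j]) << 1
                        | int(M[k, i]) << 2 | int(M[i, k]) << 3
                        | int(M[k, j]) << 4 | int(M[j, k]) << 5)
                cls = _CODE_TABLE[code]
                if cls:
                    counts[cls - 1] += 1
    return counts


def motif_census(M, labels) -> MotifCensus:
    """Census of the 13 connected triad classes.

    The excitatory view is the census of the subgraph induced by pyramidal
    cells; the inhibitory-involved view is the class-wise difference.
    """
    M = _as_binary(M)
    if np.any(np.diag(M)):
        raise ValueError("adjacency must have a zero diagonal")
    lab = _labels(M, labels)
    entire = _census_counts(M)
    exc = _census_counts(M[np.ix_(lab, lab)])
    inh = entire - exc
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(inh > 0, exc / np.maximum(inh, 1), np.nan)
    return MotifCensus(entire, exc, inh, F)


# ---------------------------------------------------------------------------
# the seventeen-variable summary
# ---------------------------------------------------------------------------

def feature_vector(M, labels) -> pd.Series:
    """The seventeen structural variables of one recurrent network.

    Returned as a Series in the fixed FEATURE_NAMES order; undefined entries
    are NaN.
    """
    M = _as_binary(M)
    lab = _labels(M, labels)
    blocks = degree_blocks(M, lab)
    f_ei = ei_balance_factor(blocks)
    P = excitatory_input_fraction(M, lab)
    p_e_hub, p_i_hub, f_rich = hub_measures(P, lab)
    c3_all = count_3cycles(M)
    c3_e = count_3cycles(M, "excitatory", lab)
    c3_inh = c3_all - c3_e
    f_cycle = c3_e / c3_inh if c3_inh > 0 else float("nan")
    M_E = M[np.ix_(lab, lab)]
    cc_all = avg_clustering(M)
    cc_e = avg_clustering(M_E)
    r_cc = cc_e / cc_all if cc_all > 0 else float("nan")
    l_all = avg_shortest_path(M)
    l_e = avg_shortest_path(M_E)
    r_l = l_e / l_all if l_all and not np.isnan(l_all) else float("nan")
    values = (*blocks[:2], blocks[2], blocks[3], f_ei,
              p_e_hub, p_i_hub, f_rich,
              c3_e, c3_inh, f_cycle,
              cc_all, cc_e, r_cc,
              l_all, l_e, r_l)
    return pd.Series(values, index=list(FEATURE_NAMES), dtype=float)
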