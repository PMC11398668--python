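"""Per-region working-memory predictions from dendritic spine counts.

Layer-2/3 basal-dendrite spine counts of 24 macaque cortical areas (packaged
as ``data/spine_counts.csv``, together with literature evidence counts for and
against delay-period activity) are mapped linearly onto association-area
pyramidal reception probabilities in [0.15, 0.25].  For each region the
two-area model is rebuilt with that probability and the delay-period duration
is simulated over repeated topology/noise draws; a region is predicted
WM-positive when its median duration reaches a persistence threshold, and the
prediction is scored against the sign of the evidence balance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from .connectivity import SENSORY, ASSOCIATION, AreaSpec, build_network
from .simulator import ProtocolSpec, run_trial
from .synapse_dynamics import SynapseParams, NoiseSpec

__all__ = [
    "RegionRecord",
    "load_spine_table",
    "spine_to_probability",
    "predict_region",
    "predict_all_regions",
    "concordance_table",
    "P_RANGE",
]

#: the spine-count extremes map onto this reception-probability range
P_RANGE = (0.15, 0.25)


@dataclass(frozen=True)
class RegionRecord:
    """One cortical region: spine count and delay-activity evidence counts."""

    name: str
    spine_count: int
    n_positive: int
    n_negative: int
    lobe: str

    def __post_init__(self) -> None:
        if self.spine_count <= 0:
            raise ValueError("spine count must be positive")
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("evidence counts must be non-negative")


def load_spine_table() -> pd.DataFrame:
    """The packaged 24-region spine-count/evidence table, verbatim."""
    with resources.files("wmnet").joinpath("data/spine_counts.csv").open() as fh:
        df = pd.read_csv(fh)
    if len(df) != 24:
        raise RuntimeError("packaged spine table must have 24 rows")
    return df


def records_from_table(df: pd.DataFrame | None = None) -> list[RegionRecord]:
    df = load_spine_table() if df is None else df
    return [RegionRecord(r.area, int(r.spine_count), int(r.n_positive),
                         int(r.n_negative), r.lobe)
            for r in df.itertuples(index=False)]


def spine_to_probability(records) -> pd.Series:
    """Linear min-max map of spine counts onto reception probabilities.

    The region with the fewest spines gets P_RANGE[0], the one with the most
    gets P_RANGE[1].
    """
    names = [r.name for r in records]
    counts = np.array([r.spine_count for r in records], dtype=float)
    lo, hi = counts.min(), counts.max()
    if hi == lo:
        raise ValueError("need at least two distinct spine counts")
    p = P_RANGE[0] + (P_RANGE[1] - P_RANGE[0]) * (counts - lo) / (hi - lo)
    return pd.Series(p, index=names, name="p_E_rec")


def predict_region(p_E_rec: float, n_reps: int = 10, seed: int = 0,
                   params: SynapseParams = SynapseParams(),
                   protocol: ProtocolSpec = ProtocolSpec(),
                   noise: NoiseSpec = NoiseSpec(),
                   dt: float = 0.02) -> np.ndarray:
    """Delay-activity durations (ms) of one region over repeated draws.

    The association area is rebuilt with the region's pyramidal reception
    probability; each repetition uses fresh topology and noise seeds derived
    from ``seed``.
    """
    if n_reps < 1:
        raise ValueError("need at least one repetition")
    assoc = replace(ASSOCIATION, p_E_rec=float(p_E_rec))
    ss = np.random.SeedSequence(seed).spawn(n_reps)
    durations = np.empty(n_reps)
    for r, child in enumerate(ss):
        topo_seed, noise_seed = (int(x) for x in child.generate_state(2))
        net = build_network(SENSORY, assoc, seed=topo_seed % (2 ** 31))
        res = run_trial(net, params, protocol, noise,
                        seed=noise_seed % (2 ** 31), dt=dt, until="delay")
        durations[r] = res.protocol.t_delay if res.censored else res.duration
    return durations


def predict_all_regions(records=None, n_reps: int = 10, seed: int = 0,
                        params: SynapseParams = SynapseParams(),
                        protocol: ProtocolSpec = ProtocolSpec(),
                        dt: float = 0.02) -> pd.DataFrame:
    """Duration samples for all 24 regions; rows = repetitions."""
    records = records_from_table() if records is None else list(records)
    probs = spine_to_probability(records)
    ss = np.random.SeedSequence(seed).spawn(len(records))
    cols = {}
    for rec, child in zip(records, ss):
        cols[rec.name] = predict_region(
            probs[rec.name], n_reps=n_reps,
            seed=int(child.generate_state(1)[0]) % (2 ** 31),
            params=params, protocol=protocol, dt=dt)
    return pd.DataFrame(cols)


def concordance_table(predictions: pd.DataFrame, records=None,
                      threshold: float | None = None) -> pd.DataFrame:
    """Score model predictions against the literature evidence.

    A region is predicted-positive when its median duration is at least
    ``threshold`` (default: half the largest observable duration in
    ``predictions``, i.e. half the delay length).  Evidence sign is
    n_positive - n_negative; regions without any evidence are 'unexplored'.
    """
    records = records_from_table() if records is None else list(records)
    if threshold is None:
        threshold = float(np.nanmax(predictions.to_numpy())) / 2.0
    rows = []
    for rec in records:
        med = float(np.median(predictions[rec.name]))
        predicted = "positive" if med >= threshold else "negative"
        balance = rec.n_positive - rec.n_negative
        if rec.n_positive == 0 and rec.n_negative == 0:
            agreement = "unexplored"
        else:
            evidence = "positive" if balance > 0 else "negative"
            agreement = "agree" if evidence == predicted else "disagree"
        rows.append({"area": rec.name, "lobe": rec.lobe,
                     "median_duration_ms": med, "predicted": predicted,
                     "evidence_balance": balance, "agreement": agreement})
    return pd.DataFrame(rows).set_index("area")
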