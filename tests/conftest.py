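"""Shared fixtures: the expensive simulation ensembles are session-scoped so
the delay-activity statistics are computed once and reused across tests."""

import numpy as np
import pytest

from wmnet.simulator import ProtocolSpec, run_noise_ensemble, run_topology_ensemble


@pytest.fixture(scope="session")
def topology_ensemble():
    """100 random topologies, one fixed noise realization, published timing.

    Durations are censored at the 4000 ms delay; the seventeen structural
    variables of each association network ride along.
    """
    return run_topology_ensemble(100, protocol=ProtocolSpec(), noise_seed=777,
                                 base_seed=5000, dt=0.1)


@pytest.fixture(scope="session")
def noise_ensemble(topology_ensemble):
    """100 noise realizations of one fixed transient-regime topology.

    The fixed network is the ensemble's upper-quartile uncensored one: a
    representative longer-lived transient whose delay activity spans many
    population-burst cycles, so its survival time varies smoothly with the
    noise (the condition the noise-randomness distribution describes).
    """
    trans = topology_ensemble[~topology_ensemble["censored"]]
    ranked = trans.sort_values("duration_ms").reset_index(drop=True)
    seed = int(ranked.iloc[int(len(ranked) * 0.75)]["topology_seed"])
    return run_noise_ensemble(100, topology_seed=seed, protocol=ProtocolSpec(),
                              base_noise_seed=100, dt=0.1)
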