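"""Delayed match-to-sample trials on the two-area network.

Protocol (times relative to trial start): a pre-cue interval, a cue window in
which all sensory pyramidal cells receive a supra-threshold constant current,
a delay period, and a match window with the same stimulus; a reward signal of
the same amplitude is delivered to association interneurons from a fixed
latency after match onset until the trial ends.  Before t = 0 the network
settles for 200 ms from the single-neuron resting equilibrium with background
noise on.

The working-memory readout is the *duration*: the time from cue removal until
the last spike of the monitored population (association pyramidal cells by
default) within the delay period.  Durations reaching the end of the delay
are flagged censored (persistent activity).

The network update interleaves exact exponential/saturating gating updates
with fixed-step RK4 on the membrane equations (synaptic current frozen within
a step); spikes are upward crossings of 0 mV and increment the presynaptic
gating variables at the step boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .connectivity import AdjacencyPair, build_network
from .hh_neuron import (resting_state, EXCITATORY_PARAMS, INHIBITORY_PARAMS,
                        IntegrationError, _rk4_step_lut, build_rate_table)
from .synapse_dynamics import SynapseParams, NoiseSpec

__all__ = [
    "ProtocolSpec",
    "SimulationResult",
    "scaled_protocol",
    "run_trial",
    "run_topology_ensemble",
    "run_noise_ensemble",
    "wm_duration",
    "per_neuron_duration",
    "classify_state",
    "rate_trace",
    "POPULATIONS",
]

#: silent/transient threshold (ms), configurable through classify_state
THETA_SILENT_MS = 200.0
#: a spike this close to the delay end marks the trial as censored
CENSOR_WINDOW_MS = 50.0

POPULATIONS = ("sensory_E", "sensory_I", "association_E", "association_I")


@dataclass(frozen=True)
class ProtocolSpec:
    """Trial phase durations (ms) and stimulus amplitude (nA)."""

    t_precue: float = 500.0
    t_cue: float = 500.0
    t_delay: float = 4000.0
    t_match: float = 500.0
    I_cue: float = 2.0
    t_reward_onset: float = 300.0     # reward latency after match onset
    t_settle: float = 200.0           # pre-trial settling, before t = 0

    def __post_init__(self) -> None:
        for name in ("t_precue", "t_cue", "t_delay", "t_match"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t_reward_onset < 0 or self.t_settle < 0:
            raise ValueError("latencies must be non-negative")

    @property
    def cue_onset(self) -> float:
        return self.t_precue

    @property
    def cue_offset(self) -> float:
        return self.t_precue + self.t_cue

    @property
    def delay_end(self) -> float:
        return self.cue_offset + self.t_delay

    @property
    def match_onset(self) -> float:
        return self.delay_end

    @property
    def t_end(self) -> float:
        return self.delay_end + self.t_match


@dataclass
class SimulationResult:
    """Raster, per-population rate traces, and the WM-duration readout."""

    spike_ids: np.ndarray          # neuron ids (global index)
    spike_times: np.ndarray        # ms, trial clock (settling < 0)
    duration: float                # ms, association-E delay activity
    censored: bool
    protocol: ProtocolSpec
    populations: dict              # name -> global index array
    rate_traces: pd.DataFrame | None = None

    def raster_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"neuron": self.spike_ids, "time_ms": self.spike_times})


# ---------------------------------------------------------------------------
# network kernel
# ---------------------------------------------------------------------------

def _csr(rows_of_lists, n_neurons):
    indptr = np.zeros(n_neurons + 1, dtype=np.int64)
    for i, lst in enumerate(rows_of_lists):
        indptr[i + 1] = indptr[i] + len(lst)
    indices = np.empty(indptr[-1], dtype=np.int64)
    for i, lst in enumerate(rows_of_lists):
        indices[indptr[i]:indptr[i + 1]] = lst
    return indptr, indices


def _build_global_csr(net: AdjacencyPair):
    """Global-index CSR input lists per channel: recurrent E, recurrent I, external E."""
    Ns, Na = net.sensory.N, net.association.N
    exc_s, exc_a = net.sensory.labels(), net.association.labels()
    is_exc = np.concatenate([exc_s, exc_a])
    n = Ns + Na
    recE, recI, extE = [[] for _ in range(n)], [[] for _ in range(n)], [[] for _ in range(n)]
    for i in range(Ns):                       # sensory receivers
        row = net.M_rec_sens[i]
        recE[i] = list(np.nonzero(row & exc_s)[0])
        recI[i] = list(np.nonzero(row & ~exc_s)[0])
        extE[i] = list(np.nonzero(net.fb[i])[0] + Ns)       # from association E
    for a in range(Na):                       # association receivers
        i = Ns + a
        row = net.M_rec_assoc[a]
        recE[i] = list(np.nonzero(row & exc_a)[0] + Ns)
        recI[i] = list(np.nonzero(row & ~exc_a)[0] + Ns)
        extE[i] = list(np.nonzero(net.ff[a])[0])            # from sensory E
    return is_exc, _csr(recE, n), _csr(recI, n), _csr(extE, n)


@njit(cache=True, fastmath=True)
def _network_kernel(n_steps, dt, t0,
                    V, n_, m_, h_, C_m, is_exc, stim_cue, stim_reward,
                    recE_ptr, recE_idx, recI_ptr, recI_idx, extE_ptr, extE_idx,
                    g_K, g_Na, g_L, E_K, E_Na, E_L,
                    g_ampa_ext, g_ampa, g_nmda, g_gaba, V_E, V_I,
                    tau_ampa, tau_rise, tau_decay, tau_gaba, Mg, alpha, w,
                    cue_on, cue_off, match_on, match_off, reward_on, trial_end,
                    I_cue, noise_events, D_p, rate_table,
                    spike_ids, spike_times):
    N = V.shape[0]
    s_ampa = np.zeros(N)
    x_nmda = np.zeros(N)
    s_nmda = np.zeros(N)
    s_gaba = np.zeros(N)
    s_noise = np.zeros(N)
    I_tot = np.zeros(N)
    dec_a = np.exp(-dt / tau_ampa)
    dec_r = np.exp(-dt / tau_rise)
    dec_g = np.exp(-dt / tau_gaba)
    n_spk = 0
    cap = spike_ids.shape[0]
    for k in range(n_steps):
        t = t0 + k * dt
        # synaptic + stimulus currents from the current gating state
        for i in range(N):
            Sa = 0.0
            Sn = 0.0
            for p in range(recE_ptr[i], recE_ptr[i + 1]):
                j = recE_idx[p]
                Sa += s_ampa[j]
                Sn += s_nmda[j]
            Sg = 0.0
            for p in range(recI_ptr[i], recI_ptr[i + 1]):
                Sg += s_gaba[recI_idx[p]]
            Se = s_noise[i]
            for p in range(extE_ptr[i], extE_ptr[i + 1]):
                Se += s_ampa[extE_idx[p]]
            B = 1.0 / (1.0 + Mg * np.exp(-0.062 * V[i]) / 3.57)
            I = -(g_ampa_ext * (V[i] - V_E) * Se
                  + g_ampa * (V[i] - V_E) * Sa
                  + g_nmda * (V[i] - V_E) * B * Sn
                  + g_gaba * (V[i] - V_I) * Sg)
            if stim_cue[i] and ((cue_on <= t < cue_off) or (match_on <= t < match_off)):
                I += I_cue
            if stim_reward[i] and (reward_on <= t < trial_end):
                I += I_cue
            I_tot[i] = I
        # NMDA gating: exact update with x frozen over the step
        for i in range(N):
            if is_exc[i]:
                kk = 1.0 / tau_decay + alpha * x_nmda[i]
                s_inf = alpha * x_nmda[i] / kk
                s_nmda[i] = s_inf + (s_nmda[i] - s_inf) * np.exp(-kk * dt)
        # membrane step and spike detection/increments
        for i in range(N):
            Vp = V[i]
            V[i], n_[i], m_[i], h_[i] = _rk4_step_lut(
                V[i], n_[i], m_[i], h_[i], I_tot[i], dt,
                C_m[i], g_K, g_Na, g_L, E_K, E_Na, E_L, rate_table)
            s_ampa[i] *= dec_a
            x_nmda[i] *= dec_r
            s_gaba[i] *= dec_g
            s_noise[i] *= dec_a
            if Vp < 0.0 <= V[i]:
                if n_spk < cap:
                    spike_ids[n_spk] = i
                    spike_times[n_spk] = t + dt
                    n_spk += 1
                if is_exc[i]:
                    s_ampa[i] += w
                    x_nmda[i] += w
                else:
                    s_gaba[i] += w
            s_noise[i] += D_p * noise_events[k, i]
        if not np.isfinite(V[0]):
            return -1 - k
    return n_spk


# ---------------------------------------------------------------------------
# trial driver
# ---------------------------------------------------------------------------

_RATE_TABLE_CACHE = []


def _rate_table() -> np.ndarray:
    if not _RATE_TABLE_CACHE:
        _RATE_TABLE_CACHE.append(build_rate_table())
    return _RATE_TABLE_CACHE[0]


def _populations(net: AdjacencyPair) -> dict:
    Ns = net.sensory.N
    return {
        "sensory_E": np.arange(net.sensory.N_E),
        "sensory_I": np.arange(net.sensory.N_E, Ns),
        "association_E": Ns + np.arange(net.association.N_E),
        "association_I": Ns + np.arange(net.association.N_E, net.association.N),
    }


def run_trial(net: AdjacencyPair, params: SynapseParams = SynapseParams(),
              protocol: ProtocolSpec = ProtocolSpec(),
              noise: NoiseSpec = NoiseSpec(),
              seed: int | None = None,
              dt: float = 0.02,
              until: str = "end",
              with_rates: bool = False,
              duration_population: str = "association_E") -> SimulationResult:
    """Run one delayed match-to-sample trial.

    ``seed`` overrides ``noise.seed`` when given.  ``until='delay'`` stops the
    simulation at the end of the delay period (the duration readout is not
    affected by the match phase); ``until='end'`` runs the full protocol.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if until not in ("end", "delay"):
        raise ValueError("until must be 'end' or 'delay'")
    noise_seed = int(noise.seed if seed is None else seed) % (2 ** 31)

    pops = _populations(net)
    N = net.sensory.N + net.association.N
    is_exc, (reE_p, reE_i), (reI_p, reI_i), (exE_p, exE_i) = _build_global_csr(net)

    C_m = np.where(is_exc, EXCITATORY_PARAMS.C_m, INHIBITORY_PARAMS.C_m).astype(float)
    rest = resting_state(EXCITATORY_PARAMS)
    V = np.full(N, rest.V)
    n_ = np.full(N, rest.n)
    m_ = np.full(N, rest.m)
    h_ = np.full(N, rest.h)

    stim_cue = np.zeros(N, dtype=np.bool_)
    stim_cue[pops["sensory_E"]] = True
    stim_reward = np.zeros(N, dtype=np.bool_)
    stim_reward[pops["association_I"]] = True

    t_stop = protocol.delay_end if until == "delay" else protocol.t_end
    t0 = -protocol.t_settle
    n_steps = int(round((t_stop - t0) / dt))
    rng = np.random.default_rng(noise_seed)
    noise_events = rng.poisson(noise.rate * dt * 1e-3,
                               size=(n_steps, N)).astype(np.uint8)
    cap = int(N * (t_stop - t0) * 0.25) + 10_000      # ~250 Hz/neuron headroom
    spike_ids = np.empty(cap, dtype=np.int64)
    spike_times = np.empty(cap, dtype=np.float64)

    hh = EXCITATORY_PARAMS
    n_spk = _network_kernel(
        n_steps, dt, t0, V, n_, m_, h_, C_m, is_exc, stim_cue, stim_reward,
        reE_p, reE_i, reI_p, reI_i, exE_p, exE_i,
        hh.g_K, hh.g_Na, hh.g_L, hh.E_K, hh.E_Na, hh.E_L,
        params.g_AMPA_ext, params.g_AMPA, params.g_NMDA, params.g_GABA,
        params.V_E, params.V_I,
        params.tau_AMPA, params.tau_NMDA_rise, params.tau_NMDA_decay,
        params.tau_GABA, params.Mg, params.alpha_nmda, params.w_spike,
        protocol.cue_onset, protocol.cue_offset,
        protocol.match_onset, protocol.match_onset + protocol.t_match,
        protocol.match_onset + protocol.t_reward_onset, protocol.t_end,
        protocol.I_cue, noise_events, noise.D_p, _rate_table(),
        spike_ids, spike_times)
    if n_spk < 0:
        step = -(n_spk + 1)
        raise IntegrationError(
            f"network integration diverged at step {step} (t = {t0 + step * dt:.2f} ms)")

    ids = spike_ids[:n_spk].copy()
    times = spike_times[:n_spk].copy()
    duration, censored = wm_duration(ids, times, pops[duration_population],
                                     protocol.cue_offset, protocol.delay_end)
    result = SimulationResult(ids, times, duration, censored, protocol, pops)
    if with_rates:
        traces = {}
        for name, idx in pops.items():
            t_bins, r = rate_trace(ids, times, idx, t_start=t0, t_end=t_stop)
            traces[name] = r
        result.rate_traces = pd.DataFrame(traces, index=pd.Index(t_bins, name="time_ms"))
    return result


# ---------------------------------------------------------------------------
# readouts
# ---------------------------------------------------------------------------

def wm_duration(spike_ids: np.ndarray, spike_times: np.ndarray,
                population: np.ndarray, cue_offset: float, delay_end: float,
                censor_window: float = CENSOR_WINDOW_MS) -> tuple[float, bool]:
    """Time from cue removal to the population's last delay-period spike.

    Returns (duration_ms, censored); duration 0 if the population is silent
    after the cue, censored True when a spike falls within the final
    ``censor_window`` ms of the delay.
    """
    spike_ids = np.asarray(spike_ids)
    spike_times = np.asarray(spike_times)
    in_pop = np.isin(spike_ids, population)
    in_window = (spike_times > cue_offset) & (spike_times <= delay_end)
    t = spike_times[in_pop & in_window]
    if t.size == 0:
        return 0.0, False
    last = float(t.max())
    return last - cue_offset, bool(last >= delay_end - censor_window)


def per_neuron_duration(spike_ids: np.ndarray, spike_times: np.ndarray,
                        population: np.ndarray, cue_offset: float,
                        delay_end: float,
                        censor_window: float = CENSOR_WINDOW_MS) -> np.ndarray:
    """WM duration of each neuron in ``population`` individually (ms)."""
    out = np.empty(len(population))
    for k, nid in enumerate(np.asarray(population)):
        out[k], _ = wm_duration(spike_ids, spike_times, np.array([nid]),
                                cue_offset, delay_end, censor_window)
    return out


def classify_state(duration: float, censored: bool,
                   theta_silent: float = THETA_SILENT_MS) -> str:
    """Delay-activity taxonomy: 'silent', 'transient' or 'persistent'."""
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if censored:
        return "persistent"
    if duration < theta_silent:
        return "silent"
    return "transient"


def rate_trace(spike_ids: np.ndarray, spike_times: np.ndarray,
               population: np.ndarray, bin_width: float = 10.0,
               smoothing: float = 0.0, t_start: float = 0.0,
               t_end: float | None = None):
    """Population firing-rate trace (Hz): spikes per bin / (bin * pop size).

    Optional boxcar smoothing over ``smoothing`` ms.  Returns (bin centers,
    rates).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    spike_ids = np.asarray(spike_ids)
    spike_times = np.asarray(spike_times)
    sel = np.isin(spike_ids, population)
    t = spike_times[sel]
    if t_end is None:
        t_end = float(t.max()) + bin_width if t.size else t_start + bin_width
    edges = np.arange(t_start, t_end + bin_width, bin_width)
    counts, _ = np.histogram(t, bins=edges)
    rates = counts / (len(population) * bin_width * 1e-3)
    if smoothing > 0:
        w = max(1, int(round(smoothing / bin_width)))
        kernel = np.ones(w) / w
        rates = np.convolve(rates, kernel, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rates


# ---------------------------------------------------------------------------
# ensemble experiments
# ---------------------------------------------------------------------------

def scaled_protocol(t_delay: float = 1500.0) -> ProtocolSpec:
    """Desk-scale trial timing for ensemble experiments.

    The pre-cue interval is shortened to 200 ms and the delay to ``t_delay``
    (default 1.5 s); cue width, amplitude and all synaptic parameters are
    untouched, so the ignition/sustain physics is that of the full protocol
    and only the censoring horizon moves.
    """
    return ProtocolSpec(t_precue=200.0, t_cue=500.0, t_delay=t_delay,
                        t_match=300.0, t_settle=200.0)


def run_topology_ensemble(n_networks: int,
                          params: SynapseParams = SynapseParams(),
                          protocol: ProtocolSpec | None = None,
                          noise: NoiseSpec = NoiseSpec(),
                          noise_seed: int = 0, base_seed: int = 0,
                          dt: float = 0.05,
                          with_features: bool = True) -> pd.DataFrame:
    """Durations across random topologies at one fixed noise realization.

    One row per network: the topology seed, the (censoring-capped) duration,
    the censored flag and, when requested, the seventeen structural variables
    of the association recurrent matrix.
    """
    from .graph_metrics import feature_vector
    from .connectivity import build_network as _build
    protocol = scaled_protocol() if protocol is None else protocol
    rows = []
    for i in range(n_networks):
        net = _build(seed=base_seed + i)
        res = run_trial(net, params, protocol, noise, seed=noise_seed,
                        until="delay", dt=dt)
        row = {"topology_seed": base_seed + i,
               "duration_ms": protocol.t_delay if res.censored else res.duration,
               "censored": res.censored}
        if with_features:
            row.update(feature_vector(net.M_rec_assoc,
                                      net.association.labels()).to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def run_noise_ensemble(n_seeds: int, topology_seed: int = 0,
                       params: SynapseParams = SynapseParams(),
                       protocol: ProtocolSpec | None = None,
                       noise: NoiseSpec = NoiseSpec(),
                       base_noise_seed: int = 0,
                       dt: float = 0.05) -> pd.DataFrame:
    """Durations across noise realizations at one fixed topology."""
    from .connectivity import build_network as _build
    protocol = scaled_protocol() if protocol is None else protocol
    net = _build(seed=topology_seed)
    rows = []
    for i in range(n_seeds):
        res = run_trial(net, params, protocol, noise,
                        seed=base_noise_seed + i, until="delay", dt=dt)
        rows.append({"noise_seed": base_noise_seed + i,
                     "duration_ms": protocol.t_delay if res.censored else res.duration,
                     "censored": res.censored})
    return pd.DataFrame(rows)
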