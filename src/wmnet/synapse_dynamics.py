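"""Synaptic gating dynamics and current assembly.

Excitatory (glutamatergic) transmission has a fast AMPA component and a slow,
voltage-dependent NMDA component; inhibitory (GABAergic) transmission is fast.
Gating variables s live on the *presynaptic* neuron and measure the proportion
of open channels at its efferent synapses:

    ds_AMPA/dt = -s/tau_AMPA  + w * sum_k delta(t - t_k)   (+ noise, external)
    dx/dt      = -x/tau_rise  + w * sum_k delta(t - t_k)
    ds_NMDA/dt = -s/tau_decay + alpha * x * (1 - s)
    ds_GABA/dt = -s/tau_GABA  + w * sum_k delta(t - t_k)

The NMDA current is attenuated by the magnesium block
B(V) = 1 / (1 + [Mg] exp(-0.062 V)/3.57).

Currents follow the depolarizing-positive convention: I_syn enters the
membrane equation with a positive sign, so AMPA/NMDA currents are positive
(depolarizing) when V < V_E and the GABA current is negative when V > V_I.

The per-spike increment w_spike and the NMDA activation rate alpha_nmda are
not biophysical constants of the model family but calibration parameters.
Two frozen calibrations ship with the package:

* the *unitary* calibration (:func:`unitary_calibrated`) makes a single
  recurrent EPSC under voltage clamp at -65 mV peak at ~71 pA (AMPA) and
  ~19 pA (NMDA), an NMDA/AMPA ratio of 26.6%, at g_AMPA = 0.11 uS and
  g_NMDA = 0.13 uS — the single-synapse benchmark scale;
* the *network* calibration (the :class:`SynapseParams` defaults) scales the
  per-spike increment up so that cue-evoked feedforward input can ignite the
  association area, and places the NMDA activation rate so that the
  delay-activity taxonomy over g_NMDA (silent near 0.05 uS, transient near
  0.13 uS, persistent near 0.15 uS at 20% association connectivity) is
  reproduced.

The two scales are mutually exclusive here: with ~16 feedforward contacts
per pyramidal cell and a 0.7 nA class-2 firing threshold, unitary-scale
synapses (~70 pA) sum to well under the threshold, so a network built on
them never expresses delay activity.  Network simulations therefore default
to the network calibration, and single-synapse benchmarks use the unitary
one; docs/methods.md discusses the discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SynapseParams",
    "unitary_calibrated",
    "GatingState",
    "NoiseSpec",
    "mg_block",
    "update_gating",
    "synaptic_current",
    "unitary_epsc_timecourse",
    "unitary_epsc_peaks",
]

#: unitary calibration: AMPA peak = g_AMPA * 65 mV * w_spike = 71 pA
W_SPIKE_UNITARY = 0.00993
#: unitary calibration: NMDA activation rate giving a 19 pA unitary NMDA
#: peak at -65 mV clamp (Mg = 1 mM) with the w_spike above; units 1/ms.
ALPHA_NMDA_UNITARY = 2.087

#: network calibration: smallest increment at which the cue reliably ignites
#: the association area (see docs/methods.md)
W_SPIKE_NETWORK = 0.02
#: network calibration: places the NMDA self-sustain boundary between
#: g_NMDA = 0.13 and 0.15 uS at 20% association connectivity
ALPHA_NMDA_NETWORK = 0.65


@dataclass(frozen=True)
class SynapseParams:
    """Synaptic conductances (uS), reversals (mV), kinetics (ms)."""

    g_AMPA_ext: float = 0.22
    g_AMPA: float = 0.11
    g_NMDA: float = 0.13
    g_GABA: float = 0.47
    V_E: float = 0.0
    V_I: float = -70.0
    tau_AMPA: float = 2.0
    tau_NMDA_rise: float = 2.0
    tau_NMDA_decay: float = 100.0
    tau_GABA: float = 10.0
    Mg: float = 1.0            # mM
    alpha_nmda: float = ALPHA_NMDA_NETWORK   # 1/ms, calibration parameter
    w_spike: float = W_SPIKE_NETWORK         # per-spike gating increment

    def __post_init__(self) -> None:
        for name in ("g_AMPA_ext", "g_AMPA", "g_NMDA", "g_GABA",
                     "tau_AMPA", "tau_NMDA_rise", "tau_NMDA_decay",
                     "tau_GABA", "Mg", "alpha_nmda", "w_spike"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.V_I < self.V_E:
            raise ValueError("V_I must be below V_E")


@dataclass(frozen=True)
class NoiseSpec:
    """Background synaptic noise: per-neuron independent Poisson event trains.

    Each event increments the neuron's external-AMPA gating by D_p.
    """

    rate: float = 2300.0   # Hz
    D_p: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0 or self.D_p < 0:
            raise ValueError("rate and D_p must be non-negative")


@dataclass
class GatingState:
    """Per-presynaptic-neuron channel-open fractions (arrays of equal length)."""

    s_AMPA_ext: np.ndarray
    s_AMPA_rec: np.ndarray
    s_NMDA: np.ndarray
    x_NMDA: np.ndarray
    s_GABA: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "GatingState":
        return cls(*(np.zeros(n) for _ in range(5)))


def unitary_calibrated(**overrides) -> SynapseParams:
    """SynapseParams under the unitary-EPSC calibration (single-synapse scale)."""
    kwargs = {"w_spike": W_SPIKE_UNITARY, "alpha_nmda": ALPHA_NMDA_UNITARY}
    kwargs.update(overrides)
    return SynapseParams(**kwargs)


def mg_block(V, Mg: float = 1.0):
    """Voltage-dependent magnesium attenuation of the NMDA conductance.

    B(V) = 1 / (1 + Mg * exp(-0.062 V) / 3.57); strictly increasing in V,
    in (0, 1] for Mg > 0 and identically 1 for Mg = 0.
    """
    if np.any(np.asarray(Mg) < 0):
        raise ValueError("Mg concentration must be non-negative")
    return 1.0 / (1.0 + Mg * np.exp(-0.062 * np.asarray(V, dtype=float)) / 3.57)


def _nmda_step(s: np.ndarray, x: np.ndarray, alpha: float, tau_decay: float,
               dt: float) -> np.ndarray:
    """Advance the saturating NMDA gating with x held constant over dt.

    ds/dt = -s/tau_decay + alpha x (1 - s) is linear in s for frozen x, so the
    step is exact for that approximation and keeps s in [0, 1].
    """
    k = 1.0 / tau_decay + alpha * x
    s_inf = np.divide(alpha * x, k, out=np.zeros_like(np.asarray(k, dtype=float)),
                      where=k > 0)
    return s_inf + (s - s_inf) * np.exp(-k * dt)


def update_gating(state: GatingState, presyn_spike_flags: np.ndarray,
                  background_events: np.ndarray, params: SynapseParams,
                  dt: float) -> GatingState:
    """Advance all gating variables by dt.

    presyn_spike_flags: boolean/integer array, spikes of each presynaptic
    neuron in this step (each increments x_NMDA, s_AMPA_*, s_GABA by w_spike).
    background_events: per-neuron additive background increments to the
    external-AMPA gating for this step (Poisson event count times the noise
    quantum D_p, already multiplied by the caller).

    Order: decay over dt, then instantaneous increments at the step boundary.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    spikes = np.asarray(presyn_spike_flags, dtype=float)
    bg = np.asarray(background_events, dtype=float)
    w = params.w_spike

    s_ext = state.s_AMPA_ext * np.exp(-dt / params.tau_AMPA) + w * spikes + bg
    s_rec = state.s_AMPA_rec * np.exp(-dt / params.tau_AMPA) + w * spikes
    x = state.x_NMDA * np.exp(-dt / params.tau_NMDA_rise) + w * spikes
    s_nmda = _nmda_step(state.s_NMDA, state.x_NMDA, params.alpha_nmda,
                        params.tau_NMDA_decay, dt)
    s_gaba = state.s_GABA * np.exp(-dt / params.tau_GABA) + w * spikes
    return GatingState(s_ext, s_rec, s_nmda, x, s_gaba)


def synaptic_current(V_post: float, gating: GatingState,
                     eps_rec: np.ndarray, eps_ext: np.ndarray,
                     params: SynapseParams,
                     is_excitatory: np.ndarray) -> float:
    """Total synaptic current (nA) onto one neuron, depolarizing-positive.

    eps_rec / eps_ext are the neuron's rows of the recurrent and external
    adjacency matrices (binary, indexed by presynaptic neuron). Recurrent
    AMPA/NMDA sums run over excitatory presynaptic neurons, GABA over
    inhibitory ones, external AMPA over excitatory neurons of the source area.
    """
    eps_rec = np.asarray(eps_rec, dtype=float)
    eps_ext = np.asarray(eps_ext, dtype=float)
    exc = np.asarray(is_excitatory, dtype=bool)
    n = gating.s_AMPA_rec.shape[0]
    if eps_rec.shape[0] != n or exc.shape[0] != n:
        raise ValueError("adjacency/gating length mismatch")
    if eps_ext.shape[0] != gating.s_AMPA_ext.shape[0]:
        raise ValueError("adjacency/gating length mismatch (external)")

    drive_E = V_post - params.V_E
    drive_I = V_post - params.V_I
    I_ampa_ext = params.g_AMPA_ext * drive_E * float(eps_ext @ gating.s_AMPA_ext)
    I_ampa_rec = params.g_AMPA * drive_E * float((eps_rec * exc) @ gating.s_AMPA_rec)
    I_nmda = (params.g_NMDA * drive_E * mg_block(V_post, params.Mg)
              * float((eps_rec * exc) @ gating.s_NMDA))
    I_gaba = params.g_GABA * drive_I * float((eps_rec * ~exc) @ gating.s_GABA)
    # Eq-defined currents g (V - E) s are outward-positive; the membrane
    # equation adds I_syn, so flip the sign to make EPSCs depolarizing.
    return -(I_ampa_ext + I_ampa_rec + I_nmda + I_gaba)


def unitary_epsc_timecourse(params: SynapseParams, V_hold: float = -65.0,
                            t_sim: float = 300.0, dt: float = 0.02):
    """AMPA and NMDA current components (pA) after one presynaptic spike.

    The postsynaptic neuron is voltage-clamped at V_hold; one excitatory
    presynaptic spike arrives at t = 0. Returns (t, I_AMPA, I_NMDA), currents
    as positive (inward EPSC) magnitudes in pA.
    """
    n_steps = int(round(t_sim / dt))
    t = np.arange(0, n_steps + 1) * dt
    # single presynaptic spike at t = 0; gating jumps by w_spike at t = 0+
    s_ampa = params.w_spike * np.exp(-t / params.tau_AMPA)
    # integrate NMDA gating
    x = params.w_spike
    s = 0.0
    s_nmda = np.zeros(n_steps + 1)
    for k in range(n_steps):
        s = float(_nmda_step(np.asarray(s), np.asarray(x), params.alpha_nmda,
                             params.tau_NMDA_decay, dt))
        x *= np.exp(-dt / params.tau_NMDA_rise)
        s_nmda[k + 1] = s
    drive = V_hold - params.V_E          # negative at hyperpolarized holding
    I_ampa = -params.g_AMPA * drive * s_ampa * 1e3          # uS*mV = nA -> pA
    I_nmda = -params.g_NMDA * drive * mg_block(V_hold, params.Mg) * s_nmda * 1e3
    return t, I_ampa, I_nmda


def unitary_epsc_peaks(params: SynapseParams, V_hold: float = -65.0,
                       t_sim: float = 300.0, dt: float = 0.02):
    """Peak AMPA and NMDA unitary EPSC magnitudes (pA) and NMDA/AMPA ratio.

    Measured under voltage clamp at V_hold after a single presynaptic spike.
    The ratio is returned as a fraction (0.266 for 26.6%), 0 if the AMPA
    component is absent.
    """
    _, I_ampa, I_nmda = unitary_epsc_timecourse(params, V_hold, t_sim, dt)
    peak_ampa = float(np.max(np.abs(I_ampa))) if I_ampa.size else 0.0
    peak_nmda = float(np.max(np.abs(I_nmda))) if I_nmda.size else 0.0
    ratio = peak_nmda / peak_ampa if peak_ampa > 0 else 0.0
    return peak_ampa, peak_nmda, ratio
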