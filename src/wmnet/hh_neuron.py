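"""Single-neuron Hodgkin-Huxley dynamics and characterization.

The neurons of the cortical model are class-2 Hodgkin-Huxley point neurons:

    C_m dV/dt = -g_K n^4 (V - E_K) - g_Na m^3 h (V - E_Na) - g_L (V - E_L) + I_syn

with gating variables y in {n, m, h} obeying

    dy/dt = alpha_y(V) (1 - y) - beta_y(V) y.

Pyramidal cells and interneurons share all parameters except the membrane
capacitance (0.5 nF vs 0.25 nF).  Voltages are in mV, time in ms, conductances
in uS, currents in nA, capacitance in nF, so that uS*mV = nA and nA/nF = mV/ms.

This module provides the rate constants, a fixed-step RK4 integrator, and the
single-neuron characterization used throughout (f-I curve, rheobase).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import brentq

__all__ = [
    "HHParams",
    "HHState",
    "EXCITATORY_PARAMS",
    "INHIBITORY_PARAMS",
    "IntegrationError",
    "rate_constants",
    "resting_state",
    "step_state",
    "simulate_constant_current",
    "firing_rate",
    "f_i_curve",
    "rheobase",
]

#: default integration step (ms); RK4 on these rate constants is stable and
#: convergent at this step (halving it changes spike counts by at most one).
DEFAULT_DT = 0.02

#: spike = upward crossing of 0 mV; crossings closer than this are one spike.
SPIKE_THRESHOLD_MV = 0.0
MIN_ISI_MS = 2.0

#: |V - V_sing| below which the removable singularities of alpha_n / alpha_m
#: are evaluated by their analytic limits.
_SINGULARITY_EPS = 1e-6


class IntegrationError(RuntimeError):
    """Raised when the fixed-step integration produces non-finite state."""


@dataclass(frozen=True)
class HHParams:
    """Membrane parameters. Defaults are the excitatory (pyramidal) set."""

    C_m: float = 0.5     # nF (0.25 for interneurons)
    g_K: float = 4.74    # uS
    g_Na: float = 12.5   # uS
    g_L: float = 0.025   # uS
    E_K: float = -80.0   # mV
    E_Na: float = 40.0   # mV
    E_L: float = -65.0   # mV

    def __post_init__(self) -> None:
        if not (self.C_m > 0):
            raise ValueError("C_m must be positive")
        for name in ("g_K", "g_Na", "g_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.E_K < self.E_L < self.E_Na):
            raise ValueError("reversal potentials must satisfy E_K < E_L < E_Na")


EXCITATORY_PARAMS = HHParams(C_m=0.5)
INHIBITORY_PARAMS = HHParams(C_m=0.25)


@dataclass
class HHState:
    """Membrane potential (mV) and channel gating fractions of one neuron."""

    V: float
    n: float
    m: float
    h: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.n, self.m, self.h], dtype=float)


# ---------------------------------------------------------------------------
# rate constants
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rates(V):
    """Six voltage-dependent channel switch rates (1/ms)."""
    x = V + 20.0
    if abs(x) < _SINGULARITY_EPS:
        a_n = 0.1  # limit of 0.01 x / (1 - exp(-x/10)) as x -> 0
    else:
        a_n = 0.01 * x / (1.0 - np.exp(-x / 10.0))
    b_n = 0.125 * np.exp(-(V + 30.0) / 80.0)
    x = V + 16.0
    if abs(x) < _SINGULARITY_EPS:
        a_m = 1.0
    else:
        a_m = 0.1 * x / (1.0 - np.exp(-x / 10.0))
    b_m = 4.0 * np.exp(-(V + 41.0) / 18.0)
    a_h = 0.07 * np.exp(-(V + 30.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-V / 10.0))
    return a_n, b_n, a_m, b_m, a_h, b_h


# Tabulated rates for the network kernel: the six rates sampled on a fine
# voltage grid; linear interpolation keeps the relative error below ~1e-6
# while avoiding six exp evaluations per RK4 stage per neuron.
RATE_TABLE_V_MIN = -300.0
RATE_TABLE_V_MAX = 100.0
RATE_TABLE_STEP = 0.01


def build_rate_table() -> np.ndarray:
    V = np.arange(RATE_TABLE_V_MIN, RATE_TABLE_V_MAX + RATE_TABLE_STEP / 2,
                  RATE_TABLE_STEP)
    table = np.empty((V.size, 6))
    for i, v in enumerate(V):
        table[i] = _rates(v)
    return table


@njit(cache=True, inline="always")
def _rates_lut(V, table):
    pos = (V - RATE_TABLE_V_MIN) / RATE_TABLE_STEP
    if pos <= 0.0:
        return (table[0, 0], table[0, 1], table[0, 2], table[0, 3],
                table[0, 4], table[0, 5])
    last = table.shape[0] - 1
    if pos >= last:
        return (table[last, 0], table[last, 1], table[last, 2],
                table[last, 3], table[last, 4], table[last, 5])
    i = int(pos)
    f = pos - i
    return (table[i, 0] + f * (table[i + 1, 0] - table[i, 0]),
            table[i, 1] + f * (table[i + 1, 1] - table[i, 1]),
            table[i, 2] + f * (table[i + 1, 2] - table[i, 2]),
            table[i, 3] + f * (table[i + 1, 3] - table[i, 3]),
            table[i, 4] + f * (table[i + 1, 4] - table[i, 4]),
            table[i, 5] + f * (table[i + 1, 5] - table[i, 5]))


@njit(cache=True, inline="always")
def _derivs_lut(V, n, m, h, I_syn, C_m, g_K, g_Na, g_L, E_K, E_Na, E_L, table):
    n = min(max(n, 0.0), 1.0)
    m = min(max(m, 0.0), 1.0)
    h = min(max(h, 0.0), 1.0)
    a_n, b_n, a_m, b_m, a_h, b_h = _rates_lut(V, table)
    I_ion = (-g_K * n ** 4 * (V - E_K)
             - g_Na * m ** 3 * h * (V - E_Na)
             - g_L * (V - E_L))
    dV = (I_ion + I_syn) / C_m
    dn = a_n * (1.0 - n) - b_n * n
    dm = a_m * (1.0 - m) - b_m * m
    dh = a_h * (1.0 - h) - b_h * h
    return dV, dn, dm, dh


@njit(cache=True, inline="always")
def _rk4_step_lut(V, n, m, h, I_syn, dt, C_m, g_K, g_Na, g_L, E_K, E_Na, E_L,
                  table):
    k1 = _derivs_lut(V, n, m, h, I_syn, C_m, g_K, g_Na, g_L, E_K, E_Na, E_L, table)
    k2 = _derivs_lut(V + 0.5 * dt * k1[0], n + 0.5 * dt * k1[1],
                     m + 0.5 * dt * k1[2], h + 0.5 * dt * k1[3],
                     I_syn, C_m, g_K, g_Na, g_L, E_K, E_Na, E_L, table)
    k3 = _derivs_lut(V + 0.5 * dt * k2[0], n + 0.5 * dt * k2[1],
                     m + 0.5 * dt * k2[2], h + 0.5 * dt * k2[3],
                     I_syn, C_m, g_K, g_Na, g_L, E_K, E_Na, E_L, table)
    k4 = _derivs_lut(V + dt * k3[0], n + dt * k3[1], m + dt * k3[2],
                     h + dt * k3[3], I_syn, C_m, g_K, g_Na, g_L, E_K, E_Na,
                     E_L, table)
    V = V + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    n = n + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    m = m + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
    h = h + dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
    n = min(max(n, 0.0), 1.0)
    m = min(max(m, 0.0), 1.0)
    h = min(max(h, 0.0), 1.0)
    return V, n, m, h


def rate_constants(V: float) -> tuple[float, float, float, float, float, float]:
    """Channel switch rates (alpha_n, beta_n, alpha_m, beta_m, alpha_h, beta_h).

    The removable singularities of alpha_n (V = -20 mV) and alpha_m
    (V = -16 mV) are evaluated by their analytic limits.
    """
    V = float(V)
    if not np.isfinite(V):
        raise ValueError("membrane potential must be finite")
    return _rates(V)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

@njit(cache=True)
def _derivs(V, n, m, h, I_syn, C_m, g_K, g_Na, g_L, E_K, E_Na, E_L):
    # gating fractions are clipped here so that RK4 substages stay physical
    # even when a rate constant is stiff (strongly hyperpolarized membrane)
    n = min(max(n, 0.0), 1.0)
    m = min(max(m, 0.0), 1.0)
    h = min(max(h, 0.0), 1.0)
    a_n, b_n, a_m, b_m, a_h, b_h = _rates(V)
    I_ion = (-g_K * n ** 4 * (V - E_K)
             - g_Na * m ** 3 * h * (V - E_Na)
             - g_L * (V - E_L))
    dV = (I_ion + I_syn) / C_m
    dn = a_n * (1.0 - n) - b_n * n
    dm = a_m * (1.0 - m) - b_m * m
    dh = a_h * (1.0 - h) - b_h * h
    return dV, dn, dm, dh


@njit(cache=True)
def _rk4_step(V, n, m, h, I_syn, dt, C_m, g_K, g_Na, g_L, E_K, E_Na, E_L):
    """One fixed-step RK4 step with I_syn held constant over dt."""
    k1 = _derivs(V, n, m, h, I_syn, C_m, g_K, g_Na, g_L, E_K, E_Na, E_L)
    k2 = _derivs(V + 0.5 * dt * k1[0], n + 0.5 * dt * k1[1],
                 m + 0.5 * dt * k1[2], h + 0.5 * dt * k1[3],
                 I_syn, C_m, g_K, g_Na, g_L, E_K, E_Na, E_L)
    k3 = _derivs(V + 0.5 * dt * k2[0], n + 0.5 * dt * k2[1],
                 m + 0.5 * dt * k2[2], h + 0.5 * dt * k2[3],
                 I_syn, C_m, g_K, g_Na, g_L, E_K, E_Na, E_L)
    k4 = _derivs(V + dt * k3[0], n + dt * k3[1], m + dt * k3[2], h + dt * k3[3],
                 I_syn, C_m, g_K, g_Na, g_L, E_K, E_Na, E_L)
    V = V + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    n = n + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    m = m + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
    h = h + dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
    # gating fractions are proportions of open channels
    n = min(max(n, 0.0), 1.0)
    m = min(max(m, 0.0), 1.0)
    h = min(max(h, 0.0), 1.0)
    return V, n, m, h


def step_state(state: HHState, params: HHParams, I_syn: float, dt: float) -> HHState:
    """Advance one neuron by dt (ms) with constant synaptic current (nA)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    V, n, m, h = _rk4_step(state.V, state.n, state.m, state.h, float(I_syn), dt,
                           params.C_m, params.g_K, params.g_Na, params.g_L,
                           params.E_K, params.E_Na, params.E_L)
    if not np.isfinite(V):
        raise IntegrationError(f"membrane potential diverged (V={V!r})")
    return HHState(V, n, m, h)


def _steady_gating(V: float) -> tuple[float, float, float]:
    a_n, b_n, a_m, b_m, a_h, b_h = _rates(V)
    return a_n / (a_n + b_n), a_m / (a_m + b_m), a_h / (a_h + b_h)


def resting_state(params: HHParams = EXCITATORY_PARAMS, I_syn: float = 0.0) -> HHState:
    """Resting equilibrium: root of dV/dt with gating at steady state."""

    def f(V: float) -> float:
        n, m, h = _steady_gating(V)
        return (-params.g_K * n ** 4 * (V - params.E_K)
                - params.g_Na * m ** 3 * h * (V - params.E_Na)
                - params.g_L * (V - params.E_L) + I_syn)

    V0 = brentq(f, params.E_K, -40.0, xtol=1e-12)
    n, m, h = _steady_gating(V0)
    return HHState(V0, n, m, h)


# ---------------------------------------------------------------------------
# constant-current characterization
# ---------------------------------------------------------------------------

@njit(cache=True)
def _run_constant_current(V, n, m, h, I, dt, n_steps, min_isi,
                          C_m, g_K, g_Na, g_L, E_K, E_Na, E_L):
    spike_times = np.empty(n_steps // 8 + 16, dtype=np.float64)
    n_spikes = 0
    last_spike = -1e9
    for k in range(n_steps):
        V_prev = V
        V, n, m, h = _rk4_step(V, n, m, h, I, dt,
                               C_m, g_K, g_Na, g_L, E_K, E_Na, E_L)
        t = (k + 1) * dt
        if V_prev < SPIKE_THRESHOLD_MV <= V and t - last_spike >= min_isi:
            if n_spikes < spike_times.size:
                spike_times[n_spikes] = t
                n_spikes += 1
            last_spike = t
    return spike_times[:n_spikes], V


def simulate_constant_current(params: HHParams, I: float, t_sim: float,
                              dt: float = DEFAULT_DT) -> np.ndarray:
    """Spike times (ms) of a neuron driven from rest by a constant current."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    rest = resting_state(params)
    n_steps = int(round(t_sim / dt))
    spikes, V_end = _run_constant_current(
        rest.V, rest.n, rest.m, rest.h, float(I), dt, n_steps, MIN_ISI_MS,
        params.C_m, params.g_K, params.g_Na, params.g_L,
        params.E_K, params.E_Na, params.E_L)
    if not np.isfinite(V_end):
        raise IntegrationError("constant-current run diverged")
    return spikes


def firing_rate(params: HHParams, I: float, t_sim: float = 2000.0,
                t_discard: float = 200.0, dt: float = DEFAULT_DT) -> float:
    """Steady firing rate (Hz): spikes after t_discard / counted window."""
    if not t_sim > t_discard >= 0:
        raise ValueError("need t_sim > t_discard >= 0")
    spikes = simulate_constant_current(params, I, t_sim, dt=dt)
    count = int(np.sum(spikes > t_discard))
    return count / ((t_sim - t_discard) / 1000.0)


def f_i_curve(params: HHParams, currents: np.ndarray, t_sim: float = 2000.0,
              t_discard: float = 200.0, dt: float = DEFAULT_DT) -> np.ndarray:
    """Firing rate (Hz) at each of a sweep of constant currents (nA)."""
    return np.array([firing_rate(params, I, t_sim, t_discard, dt)
                     for I in np.asarray(currents, dtype=float)])


def _fires(params: HHParams, I: float, dt: float,
           min_spikes: int = 5, t_sim: float = 2000.0, t_discard: float = 200.0) -> bool:
    """Sustained repetitive firing: >= min_spikes after the discard window."""
    spikes = simulate_constant_current(params, I, t_sim, dt=dt)
    return int(np.sum(spikes > t_discard)) >= min_spikes


def rheobase(params: HHParams, I_lo: float = 0.1, I_hi: float = 2.0,
             resolution: float = 0.01, dt: float = DEFAULT_DT) -> float:
    """Minimal constant current (nA) producing sustained repetitive firing.

    Bisects [I_lo, I_hi]; I_lo must be silent and I_hi must fire.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if _fires(params, I_lo, dt):
        raise ValueError(f"lower bracket I_lo={I_lo} already fires")
    if not _fires(params, I_hi, dt):
        raise ValueError(f"upper bracket I_hi={I_hi} does not fire")
    while I_hi - I_lo > resolution:
        mid = 0.5 * (I_lo + I_hi)
        if _fires(params, mid, dt):
            I_hi = mid
        else:
            I_lo = mid
    return 0.5 * (I_lo + I_hi)
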