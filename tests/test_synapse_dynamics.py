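"""Synaptic gating kinetics, magnesium block, current assembly, EPSC shapes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wmnet import synapse_dynamics as syn


class TestMgBlock:
    def test_reference_values(self):
        assert syn.mg_block(0.0, 1.0) == pytest.approx(3.57 / 4.57, rel=1e-12)
        assert syn.mg_block(-123.0, 0.0) == 1.0
        # direct numeric evaluation of the blocking factor at rest
        expect = 1.0 / (1.0 + np.exp(-0.062 * -65.0) / 3.57)
        assert syn.mg_block(-65.0, 1.0) == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(0.0597, abs=5e-4)

    def test_monotone_in_voltage_and_magnesium(self):
        V = np.linspace(-100, 60, 161)
        for Mg in (0.5, 1.0, 2.0):
            b = syn.mg_block(V, Mg)
            assert (np.diff(b) > 0).all()
            assert ((b > 0) & (b <= 1)).all()
        for v in (-80.0, -50.0, 0.0):
            bs = [float(syn.mg_block(v, mg)) for mg in (0.0, 0.5, 1.0, 2.0)]
            assert all(a > b for a, b in zip(bs, bs[1:]))

    def test_negative_mg_rejected(self):
        with pytest.raises(ValueError):
            syn.mg_block(0.0, -1.0)


class TestGatingUpdates:
    def test_pure_exponential_decay_gaba(self):
        params = syn.SynapseParams()
        state = syn.GatingState.zeros(1)
        state.s_GABA[:] = 0.8
        n_steps = 100
        dt = params.tau_GABA / n_steps
        for _ in range(n_steps):
            state = syn.update_gating(state, [0], [0.0], params, dt)
        assert state.s_GABA[0] == pytest.approx(0.8 / np.e, rel=0.01)

    def test_single_spike_jumps_x_then_decays(self):
        params = syn.SynapseParams()
        state = syn.GatingState.zeros(1)
        state = syn.update_gating(state, [1], [0.0], params, 0.02)
        assert state.x_NMDA[0] == pytest.approx(params.w_spike, rel=1e-6)
        for _ in range(100):                       # 2 ms = one rise constant
            state = syn.update_gating(state, [0], [0.0], params, 0.02)
        assert state.x_NMDA[0] == pytest.approx(params.w_spike / np.e, rel=0.01)

    def test_nmda_saturation_bound(self):
        params = syn.SynapseParams()
        state = syn.GatingState.zeros(1)
        state.s_NMDA[:] = 1.0
        values = []
        for _ in range(200):
            state = syn.update_gating(state, [0], [0.0], params, 1.0)
            values.append(state.s_NMDA[0])
        assert all(0.0 <= v <= 1.0 for v in values)
        # decays toward 0 with tau_NMDA_decay = 100 ms
        assert values[99] == pytest.approx(np.exp(-1.0), rel=0.01)

    def test_background_events_feed_external_gating_only(self):
        params = syn.SynapseParams()
        state = syn.GatingState.zeros(2)
        state = syn.update_gating(state, [0, 0], [0.005, 0.0], params, 0.02)
        assert state.s_AMPA_ext[0] == pytest.approx(0.005)
        assert state.s_AMPA_rec[0] == 0.0
        assert state.s_AMPA_ext[1] == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_gating_nonnegative_under_random_trains(self, seed):
        rng = np.random.default_rng(seed)
        params = syn.SynapseParams()
        state = syn.GatingState.zeros(4)
        for _ in range(200):
            spikes = rng.integers(0, 2, size=4)
            bg = rng.poisson(0.05, size=4) * 0.005
            state = syn.update_gating(state, spikes, bg, params, 0.1)
            for arr in (state.s_AMPA_ext, state.s_AMPA_rec, state.s_NMDA,
                        state.x_NMDA, state.s_GABA):
                assert (arr >= 0).all()
            assert (state.s_NMDA <= 1.0).all()


class TestSynapticCurrent:
    def _setup(self, n=4):
        gating = syn.GatingState.zeros(n)
        eps = np.ones(n)
        is_exc = np.array([True, True, True, False])
        return gating, eps, is_exc

    def test_zero_gating_zero_current(self):
        gating, eps, is_exc = self._setup()
        I = syn.synaptic_current(-65.0, gating, eps, np.zeros(4),
                                 syn.SynapseParams(), is_exc)
        assert I == 0.0

    def test_no_excitatory_drive_at_reversal(self):
        gating, eps, is_exc = self._setup()
        gating.s_AMPA_rec[:] = 0.5
        gating.s_NMDA[:] = 0.5
        gating.s_AMPA_ext[:] = 0.5
        I = syn.synaptic_current(0.0, gating, eps, eps, syn.SynapseParams(),
                                 is_exc)
        assert I == pytest.approx(0.0)

    def test_unit_gaba_current_magnitude(self):
        """One GABA synapse at s = 1, V = -65: |I| = 0.47 uS * 5 mV = 2.35 nA."""
        gating, eps, is_exc = self._setup()
        gating.s_GABA[3] = 1.0
        I = syn.synaptic_current(-65.0, gating, eps, np.zeros(4),
                                 syn.SynapseParams(), is_exc)
        assert I == pytest.approx(-2.35, rel=1e-9)     # hyperpolarizing

    def test_signs_of_drive(self):
        gating, eps, is_exc = self._setup()
        gating.s_AMPA_rec[:2] = 0.3
        I_exc = syn.synaptic_current(-65.0, gating, eps, np.zeros(4),
                                     syn.SynapseParams(), is_exc)
        assert I_exc > 0                                # EPSC depolarizes
        gating2, _, _ = self._setup()
        gating2.s_GABA[3] = 0.3
        I_inh = syn.synaptic_current(-30.0, gating2, eps, np.zeros(4),
                                     syn.SynapseParams(), is_exc)
        assert I_inh < 0

    def test_length_mismatch_rejected(self):
        gating, eps, is_exc = self._setup()
        with pytest.raises(ValueError):
            syn.synaptic_current(-65.0, gating, eps[:3], np.zeros(4),
                                 syn.SynapseParams(), is_exc[:3])


class TestUnitaryEPSC:
    def test_unitary_calibration_meets_benchmarks(self):
        peaks = syn.unitary_epsc_peaks(syn.unitary_calibrated())
        assert peaks[0] == pytest.approx(71.0, rel=0.10)
        assert peaks[1] == pytest.approx(19.0, rel=0.10)
        assert peaks[2] * 100 == pytest.approx(26.6, abs=2.0)

    def test_no_nmda_conductance_no_nmda_peak(self):
        peaks = syn.unitary_epsc_peaks(syn.unitary_calibrated(g_NMDA=0.0))
        assert peaks[1] == 0.0 and peaks[2] == 0.0

    def test_peaks_scale_linearly_with_w(self):
        p1 = syn.unitary_epsc_peaks(syn.SynapseParams())
        ref = syn.unitary_epsc_peaks(syn.unitary_calibrated())
        scale = syn.SynapseParams().w_spike / syn.W_SPIKE_UNITARY
        assert p1[0] == pytest.approx(ref[0] * scale, rel=1e-6)

    def test_nmda_outlasts_ampa(self):
        """Slow NMDA decay: its half-decay time exceeds the AMPA one."""
        t, I_ampa, I_nmda = syn.unitary_epsc_timecourse(syn.unitary_calibrated())

        def half_decay(trace):
            peak_idx = int(np.argmax(np.abs(trace)))
            peak = abs(trace[peak_idx])
            below = np.flatnonzero(np.abs(trace[peak_idx:]) < peak / 2)
            return t[peak_idx + below[0]] - t[peak_idx]

        assert half_decay(I_nmda) > 5 * half_decay(I_ampa)


def test_params_validation():
    with pytest.raises(ValueError):
        syn.SynapseParams(g_NMDA=-0.1)
    with pytest.raises(ValueError):
        syn.SynapseParams(V_I=10.0)
    with pytest.raises(ValueError):
        syn.NoiseSpec(rate=-1.0)
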