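# wmnet default run configuration.
#
# All values are the published model constants. Any subset may be overridden
# in a user config; omitted fields fall back to these defaults.
#
# Calibration provenance (see docs/methods.md, "Synaptic calibration"):
#   synapse.w_spike = 0.02 and synapse.alpha_nmda = 0.65 are the NETWORK
#   calibration, frozen so that the cue ignites the association area and the
#   delay-activity taxonomy over g_NMDA (silent 0.05 / transient 0.13 /
#   persistent 0.15 uS) is expressed.
#   The UNITARY calibration (w_spike = 0.00993, alpha_nmda = 2.087)
#   reproduces single-synapse EPSC benchmarks (71 pA AMPA / 19 pA NMDA at
#   -65 mV clamp) and is available as
#   wmnet.synapse_dynamics.unitary_calibrated().
neuron:
  C_m_excitatory: 0.5
  C_m_inhibitory: 0.25
  g_K: 4.74
  g_Na: 12.5
  g_L: 0.025
  E_K: -80.0
  E_Na: 40.0
  E_L: -65.0
synapse:
  g_AMPA_ext: 0.22
  g_AMPA: 0.11
  g_NMDA: 0.13
  g_GABA: 0.47
  V_E: 0.0
  V_I: -70.0
  tau_AMPA: 2.0
  tau_NMDA_rise: 2.0
  tau_NMDA_decay: 100.0
  tau_GABA: 10.0
  Mg: 1.0
  alpha_nmda: 0.65
  w_spike: 0.02
connectivity:
  sensory:
    name: sensory
    N_E: 80
    N_I: 20
    p_E_rec: 0.05
    p_I_rec: 0.2
    p_E_ext: 0.05
    p_I_ext: 0.05
  association:
    name: association
    N_E: 80
    N_I: 20
    p_E_rec: 0.2
    p_I_rec: 0.2
    p_E_ext: 0.2
    p_I_ext: 0.05
protocol:
  t_precue: 500.0
  t_cue: 500.0
  t_delay: 4000.0
  t_match: 500.0
  I_cue: 2.0
  t_reward_onset: 300.0
  t_settle: 200.0
noise:
  rate: 2300.0
  D_p: 0.005
  seed: 0
seeds:
  topology: 0
  noise: 0
output_dir: wmnet-out
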