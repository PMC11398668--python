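# Methods

## Model overview

`wmnet` simulates a two-area cortical circuit performing a delayed
match-to-sample working-memory (WM) task.  Each area contains N_E = 80
pyramidal cells and N_I = 20 interneurons, modeled as class-2 Hodgkin-Huxley
(HH) point neurons

    C_m dV/dt = -g_K n^4 (V - E_K) - g_Na m^3 h (V - E_Na) - g_L (V - E_L) + I_syn

with C_m = 0.5 nF (pyramidal) / 0.25 nF (interneuron), g_K = 4.74 uS,
g_Na = 12.5 uS, g_L = 0.025 uS, E_K = -80 mV, E_Na = 40 mV, E_L = -65 mV.
The voltage-dependent switch rates alpha_y(V), beta_y(V) of the gating
variables n, m, h place the resting potential at -65 mV and the firing
threshold near 0.7 nA; the f-I curve is discontinuous (class-2), with firing
onset at >= 10 Hz and 52.7 Hz at 2 nA.  Because class-2 neurons ignore weak
fluctuating input, the background-noise regime leaves the network silent
between trials, which is what makes the delay-activity readout clean.

Synaptic transmission follows the standard conductance-based recurrent
cortical circuit family: recurrent excitation through fast AMPA
(tau = 2 ms) and slow, saturating, Mg-blocked NMDA (rise 2 ms, decay
100 ms) channels; recurrent inhibition through GABA_A (tau = 10 ms);
cross-area excitation through AMPA only.  Gating variables live on the
presynaptic neuron; each spike increments them by w_spike, and the NMDA
channel activates at rate alpha_nmda * x * (1 - s), which saturates at high
presynaptic rates.  Conductances default to g_AMPA,ext = 0.22,
g_AMPA = 0.11, g_NMDA = 0.13, g_GABA = 0.47 uS; [Mg] = 1 mM.

Connectivity is random and binary with *reception* probabilities (row =
receiving neuron): pyramidal cells receive intra-area contacts with
probability 5% (sensory area) or 20% (association area); interneurons with
20% in either area.  Cross-area projections originate from pyramidal cells
only: feedforward (sensory -> association) contacts association pyramidal
cells at 20%; feedback (association -> sensory) contacts sensory pyramidal
cells and interneurons at 5% each.  Self-connections are excluded.

The trial protocol is 500 ms pre-cue, 500 ms cue (2 nA constant current to
all sensory pyramidal cells), 4000 ms delay, 500 ms match (same stimulus),
with a reward signal of the same amplitude to association interneurons from
300 ms after match onset to trial end.  Background noise — per-neuron
independent Poisson trains at 2300 Hz, each event incrementing the external
AMPA gating by D_p = 0.005 — runs throughout, including a 200 ms settling
interval before the trial clock starts.  The WM readout is the *duration*:
time from cue offset to the last association-pyramidal spike inside the
delay, censored at the delay end (a spike in the final 50 ms flags the trial
persistent).  Durations below 200 ms are classed silent, censored trials
persistent, everything else transient.

## Numerics

* Fixed-step RK4 on the membrane equations, default dt = 0.02 ms
  (ensemble experiments run at 0.05-0.1 ms, below); gating variables are
  clipped to [0, 1] at substage evaluations and after each step, which keeps
  the integrator bounded even in the stiff, strongly hyperpolarized regime.
  Halving dt changes the spike count of a 1 s, 2 nA trial by at most one.
* Synaptic gating uses exact exponential decay plus instantaneous per-spike
  increments; the saturating NMDA equation is advanced by the exact solution
  of the linearized step (x frozen over dt), which cannot leave [0, 1].
* The network kernel evaluates the six HH rate functions from a table
  sampled every 0.01 mV with linear interpolation (relative error ~1e-6);
  the single-neuron API evaluates them analytically.  The removable
  singularities of alpha_n (V = -20 mV) and alpha_m (V = -16 mV) are
  evaluated by their limits within 1e-6 mV.
* Spikes are upward crossings of 0 mV; spike counting uses a 2 ms minimum
  inter-spike interval.  Rheobase is bisected on [0.1, 2.0] nA declaring
  "sustained firing" at >= 5 spikes in a 2 s trial after a 200 ms discard.
* All randomness flows through numpy Generators seeded from explicit
  topology/noise seeds; identical seeds give bit-identical rasters.

## Synaptic calibration: the unitary/network tension

w_spike and alpha_nmda are calibration parameters, not stated constants.
Two frozen calibrations ship:

* **Unitary calibration** (w_spike = 0.00993, alpha_nmda = 2.087): a single
  presynaptic spike onto a neuron voltage-clamped at -65 mV produces a
  71 pA AMPA peak and a 19 pA NMDA peak — an NMDA/AMPA ratio of 26.6%, the
  single-synapse electrophysiological benchmark scale.
* **Network calibration** (w_spike = 0.02, alpha_nmda = 0.65; the
  `SynapseParams` defaults): chosen once so the network expresses the three
  delay-activity regimes at 20% association connectivity — silent at
  g_NMDA = 0.05 uS, transient at 0.13 uS, persistent at 0.15 uS.

The two scales cannot coincide in this model.  An association pyramidal cell
has ~16 feedforward contacts; at the unitary scale, cue-driven sensory
firing (~50-70 Hz) plus background noise delivers at most ~0.6 nA of mean
depolarizing current, which self-limits (the AMPA driving force shrinks as
the cell depolarizes) below the ~0.7 nA class-2 ignition threshold: the
association area never fires a single spike, for any g_NMDA.  Igniting the
area through its anatomical pathway requires per-spike increments roughly
twice the unitary scale.  We therefore treat the unitary amplitudes as a
single-synapse benchmark (used in the EPSC measurements) and run all
network simulations at the network calibration; both are exposed in config
and either can be overridden.

## Desk-scale ensemble conditions

Full-scale reference experiments (1000-network ensembles, 100 repetitions
per cortical region) are out of desk reach; the packaged experiments use:

* `scaled_protocol()`: 200 ms pre-cue, 500 ms cue, shortened delay
  (1500 ms default; 2000 ms for the per-region predictions, so that the
  persistence threshold — half the delay — sits well above the typical
  transient survival time of ~0.5-1 s, as it does at full scale).  Cue
  physics and ignition are untouched; only the censoring horizon moves.
* The duration-distribution dichotomy uses the full 4000 ms delay: a
  topology ensemble of 100 networks at one fixed noise realization, and a
  noise ensemble of 100 realizations at one fixed topology.  The fixed
  topology is the ensemble's upper-quartile uncensored network, i.e. a
  representative longer-lived transient.  (The exact-median network exposes
  a measurement artifact: when activity dies after only a few population
  bursts, survival times quantize onto the burst cycle and a dip test
  flags that ~30 ms comb as multimodal; a longer-lived transient spans
  many cycles and its survival time varies smoothly with the noise.)
* Per-region predictions use 10 repetitions over the 24-region spine-count
  table.
* Network trials at dt = 0.05 ms (ensembles 0.1 ms); spike counts at these
  steps differ from dt = 0.02 by a few percent, well inside the
  seed-to-seed variability that the ensembles average over.
* Unimodality/bimodality is assessed with the Hartigan dip statistic
  (implemented in `stats_analysis`; no installed library provides it),
  calibrated by a uniform-null bootstrap.

Synthetic-data caveat: the generator produces Erdos-Renyi-type random
connectivity with the stated class-specific reception probabilities.  Real
cortical microcircuits carry distance- and type-dependent structure,
weighted synapses and plasticity, none of which the ensembles emulate, so
passing ensemble tests demonstrates the structure-function machinery on the
model's own assumptions, not on biological connectomes.

## Structural metrics

All metrics run on the association-area recurrent matrix (row = receiver)
and its node labels, in three views: entire network, excitatory-induced
subgraph, and inhibitory-involved remainder (entire minus excitatory,
class-wise).  The seventeen-variable summary: four block edge counts
(source class -> target class), the E/I balance factor
(d_EtoE + d_ItoI)/(d_EtoI + d_ItoE), hub fractions (share of each class
whose excitatory-input fraction strictly exceeds 0.8) and their ratio,
3-cycle counts (trace(M^3)/3) for the excitatory and inhibitory-involved
views and their ratio, and average clustering / shortest-path length for
the entire and excitatory views plus their ratios.  Choices worth noting:

* Local clustering uses the standard denominator k_i(k_i - 1) on the
  undirected projection; nodes of degree < 2 contribute 0.
* Directed shortest paths average over reachable ordered pairs only; the
  unreachable count is reported alongside.
* The hub threshold comparison is strict (> 0.80), and hub fractions are
  normalized within each class (N_E or N_I).
* Triad motifs: the 13 connected 3-node digraph classes, ordered by the
  standard triad-significance-profile convention (021D, 021U, 021C, 111D,
  111U, 030T, 030C, 120D, 120U, 120C, 201, 210, 300) — three 2-edge, four
  3-edge, five 4/5-edge classes and the complete triad.  Classification is
  by canonical form over the six node permutations; the excitatory view is
  the census of the pyramidal-induced subgraph and the inhibitory-involved
  view the class-wise difference.
* 4-cycle counts (used to check that cycle counts of different girths track
  each other) correct trace(M^4) for degenerate closed walks through mutual
  dyads: C4 = (tr M^4 - sum_i (2 b_i^2 - b_i))/4, b_i = mutual partners of
  node i; the formula is validated against brute-force enumeration.
* Undefined ratios (zero denominators, no reachable pairs, no inputs)
  propagate as NaN and are median-imputed, with counts logged, only at the
  regression step.

## Structure-function statistics

Durations enter as ln(duration + 1 ms), censored trials at the delay
length.  Features are z-scored so coefficient magnitudes are comparable;
the ridge objective (1/n)||y - beta0 - X beta||^2 + lambda ||beta||^2 with
unpenalized intercept is solved in closed form.  lambda comes from 5-fold
seeded cross-validation on a logarithmic grid (1e-3 ... 1e3); the default
selection takes the largest lambda within one standard error of the CV
minimum (prefer shrinkage when the data cannot distinguish fits), with the
plain minimum available as an option.  Feature importance is ranked by
|beta|, ties keeping input order.  Spearman correlations use average ranks.

## Per-region anatomy predictions

The packaged 24-region table of layer-2/3 basal-dendrite spine counts and
literature evidence counts is reproduced verbatim from its source,
including its idiosyncratic lobe assignments (TEO under Occipital, area 5
under Prefrontal).  Spine counts map linearly onto association pyramidal
reception probabilities in [0.15, 0.25] (minimum count -> 0.15, maximum ->
0.25).  Each region is simulated with fresh topology and noise seeds per
repetition; a region is predicted WM-positive when its median duration
reaches half the delay length (configurable), and predictions are scored
against the sign of (positive - negative) evidence counts, with regions
lacking any evidence labeled unexplored.

## Known limitations

* The unitary-EPSC scale and network ignition are mutually inconsistent at
  the published connectivity and threshold (discussed above); the package
  makes the tension explicit rather than hiding it in one compromise
  parameter set.
* The interneuron step-onset rheobase measures ~0.63 nA, slightly below the
  nominal common 0.7 nA threshold: with C_m = 0.25 nF the membrane is
  faster and a current step ignites the subcritical-Hopf limit cycle a
  little below the linear-stability point (0.66 nA; the pyramidal cell's is
  0.69 nA).  The bisection API reports what a step-protocol experiment
  would measure.
* Transition boundaries (which g_NMDA values sustain activity, which
  regions classify positive) are sensitive to the network calibration;
  ensemble statistics (correlation signs, bimodality) are robust across the
  calibration neighborhood, point classifications less so.
* The within-class interneuron wiring density d_ItoI shows no positive
  correlation with duration here (Spearman ~ -0.15 at n = 100, consistent
  with zero): with interneuron firing dominated by the dense E->I drive,
  the disinhibition chain (I->I wiring -> less inhibition -> longer
  durations) is too weak to surface at this calibration, unlike the other
  three block degrees whose signs are robust.
* No synaptic plasticity, receptor desensitization, multi-item memoranda or
  oscillatory readouts; the duration scalar is the only functional output.
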