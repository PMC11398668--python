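# wmnet

A spiking-network model of working memory (WM) in a two-area cortical
circuit, with a structural-metric suite and structure-function analysis.

During a delayed match-to-sample task, association cortex (e.g. prefrontal)
holds a memorandum as delay-period persistent spiking while early sensory
cortex falls silent after the cue.  `wmnet` reproduces this division of
labor in a minimal circuit — a sensory and an association area of 80
Hodgkin-Huxley pyramidal cells + 20 interneurons each, coupled by AMPA,
NMDA and GABA_A conductance synapses and random binary connectivity — and
then asks the question the package exists for: *which features of the local
wiring decide how long delay activity survives?*

The central readout of every trial is the **WM duration**: the time from
cue offset until the last spike of the association pyramidal population
within the delay period, censored at the delay length.  Trials classify as
*silent* (< 200 ms), *transient*, or *persistent* (activity reaches the end
of the delay).  Across random network realizations the package quantifies
each association network by seventeen structural variables — block edge
counts d_E→E, d_E→I, d_I→E, d_I→I; the excitation-inhibition balance factor

    F_E/I = (d_E→E + d_I→I) / (d_E→I + d_I→E);

excitatory/inhibitory hub fractions (neurons whose excitatory input share
P_i = k_E/(k_E+k_I) exceeds 80%); directed 3-cycle counts of the excitatory
subnetwork and the inhibitory-involved remainder; and small-world measures
(clustering coefficient ⟨Cc⟩ and mean shortest path ⟨l⟩ on the entire and
excitatory views) — plus the census of the 13 connected triad motifs.
Durations are linked to structure by Spearman correlation and by ridge
regression of ln(duration) on the z-scored features,

    ln(D) = β₀ + Σᵢ βᵢ Xᵢ,   minimizing  (1/n)‖y − β₀ − Xβ‖² + λ‖β‖²,

with λ from cross-validation and |βᵢ| ranking feature importance.  Finally,
a packaged table of layer-2/3 basal-dendrite spine counts for 24 macaque
cortical areas is mapped linearly onto association connectivities in
[0.15, 0.25], yielding per-region predictions of WM persistence that are
scored against literature evidence.

See `docs/methods.md` for the full model description, parameter tables,
numerical choices and known limitations — including the deliberate use of
two synaptic calibrations (a unitary-EPSC scale and a network scale).

## Worked example

Run one delayed match-to-sample trial on the published geometry (seeds make
it exactly reproducible) and compute the structural profile of the same
network:

```
$ wmnet simulate --fixture standard --topology-seed 3 --noise-seed 4 --out run1
duration 2275.5 ms (transient)

$ wmnet fixtures --kind standard --seed 3 --out run1
$ wmnet metrics --matrix run1/M_rec_association.txt --n-exc 80 --out run1
d_EtoE       1275.000000
d_EtoI        336.000000
d_ItoE        280.000000
d_ItoI         80.000000
F_EI            2.199675
P_E_hub         0.575000
P_I_hub         0.450000
F_richhub       1.277778
C3_E         1397.000000
C3_inh       1144.000000
F_cycle         1.221154
Cc_all          0.359609
Cc_E            0.366648
R_Cc            1.019574
L_all           1.817677
L_E             1.822785
R_L             1.002810
```

Reading the output: this network carried the cue into the delay period for
~2.3 s before falling silent — a *transient* trial.  Its association area
has 1275 E→E recurrent contacts against 336 + 280 cross-class ones
(balance factor F_E/I ≈ 2.20), and 1397 of its 2541 directed 3-cycles run
entirely through pyramidal cells (F_cycle ≈ 1.22).  Across an ensemble of such networks
(`wmnet sweep`, or `run_topology_ensemble` from Python), longer-lived
trials systematically come from networks with more within-class edges,
higher F_E/I, more excitatory cycles and a more small-world excitatory
subnetwork; `wmnet regress` quantifies the same pattern with ridge
coefficients.

The per-region anatomy pipeline runs as

```
$ wmnet predict-regions --reps 10 --seed 0 --out regions
```

writing per-region duration samples and an agree/disagree/unexplored
concordance table against the packaged evidence counts.

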