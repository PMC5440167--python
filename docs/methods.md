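# Methods

## Passive compartmental model

Each projection neuron (PN) is a passive cable tree. The skeleton (SWC, µm)
is inflated into cylinder cables, one per inter-branchpoint path, with the
cable diameter set to twice the mean node radius along the path and the cable
length to the summed inter-node Euclidean distances. Cables are divided into
`n = max(1, ceil(L_elec / 0.1))` equal compartments, where
`L_elec = length / λ(d)` and `λ(d) = √(R_m·d / 4R_a)`; a cable whose total
electrotonic length falls below 1e-4 is merged into its parent's distal
compartment with its membrane area conserved. The soma is a single cylinder
with length = diameter = 2×soma radius attached at the root; "somatic"
recordings refer to this compartment. Compartment membrane area is the
lateral cylinder area, so total model area equals total cable area exactly.

Membrane parameters are uniform and passive: specific membrane resistance
R_m = 20.8 kΩ·cm², capacitance C_m = 0.8 µF/cm², axial resistivity
R_a = 266.1 Ω·cm (the published whole-cell fit for antennal-lobe PNs; the
`cell3` preset). Fits for the other two published cells were not printed at
the source, so `membrane_preset('cell1'/'cell2')` requires explicit values;
the robustness of downstream conclusions is instead exercised with ±30% R_m
and ±20% R_a variants in the test suite, which leave the sign of the
ipsi/contra uEPSP difference unchanged.

The resting potential is E_rest = −60 mV and the synaptic reversal is
E_syn = 0 mV (cholinergic ORN input). Neither value affects any reported
statistic beyond setting the driving force, since all amplitudes are measured
as differences from rest.

### Synaptic conductance

A synaptic event opens a true (voltage-dependent-current) conductance
`g(t) = g_max · N · (e^(−t/τ_d) − e^(−t/τ_r))` with τ_r = 0.2 ms,
τ_d = 1.1 ms, normalized so the peak equals g_max = 0.1 nS (the value that
yields realistic ~5 mV unitary EPSPs). The analytic peak time is
`t* = τ_r τ_d/(τ_d−τ_r) · ln(τ_d/τ_r) ≈ 0.417 ms`. Equal time constants fall
back to the alpha-function limit. In the synapse-count-equalized experiments
g_max is reduced to 0.0958 nS, which keeps the mean unitary EPSP unchanged
while making connection strengths uniform.

### Integration

The tree is integrated with backward Euler at dt = 25 µs. The per-step linear
system is tree-structured and solved exactly in O(n) by Hines-ordered
elimination (children eliminated into parents from the leaves up, voltages
back-substituted from the root down); the synaptic conductance is evaluated
at the step start, keeping the step unconditionally stable at linear cost.
The inner loop is numba-compiled. Verification: a single compartment recovers
τ_m = R_m·C_m = 16.64 ms to <0.1%; a sealed cylinder matches Rall's
`R_in = R_∞·coth(L/λ)` to <0.5% at mesh bound 0.01; the somatic response to
a synaptic event matches an independent stiff ODE solution (`solve_ivp`,
rtol 1e-8) to <0.5%; halving dt or the mesh bound moves peaks by <0.2%.
Steady-state quantities (input resistance, transfer resistance) are computed
directly from the sparse conductance matrix.

### Measurement protocols

* **mEPSP** — one synaptic event in isolation; amplitude = peak − rest at the
  soma and at the synapse's own compartment; attenuation = somatic/dendritic
  amplitude. A synapse's position within its compartment is collapsed to the
  compartment centre (below mesh resolution by construction).
* **uEPSP** — synchronous activation of all synapses of one ORN; somatic
  peak − rest.
* **Summation efficacy** — uEPSP / Σ somatic mEPSPs. For a passive tree with
  fixed reversal this is ≤ 1. Note a subtlety of the peak-based definition:
  because somatic mEPSP peaks from different dendritic locations occur at
  slightly different times, the efficacy of a spatially spread connection
  stays a little below 1 (0.3–3% on our synthetic cells) even in the
  vanishing-conductance limit where summation is perfectly linear. The clean
  g→0 limit of exactly 1 holds for co-located synapses.
* **Input resistance per cable** — measured at each cable's middle
  compartment.
* **µ** — time-averaged somatic depolarization over the 200 ms stimulus
  window (trials run 200 ms longer so voltages decay, but µ is defined on the
  window).

## Synthetic data generator

The generator emulates a bilateral glomerulus reconstruction: 27 left + 26
right ORNs (one per side unilateral, connecting only on its home side), 3
left + 2 right PNs — hence 53×5 = 265 cells of which 260 are connected.
Synapse counts follow

```
count_ij = max(1, round(base · r^[ipsi] · exp(f_i^t) · d_j · ε_ij))
```

* `r = 1.35` — the ipsilateral/contralateral mean ratio;
* `f_i^t` — a per-ORN latent log-strength drawn independently for each
  *target side* t with SD 0.22. Drawing per target side (rather than one
  value per ORN) is the minimal mechanism that makes normalized contributions
  correlated between PNs on the same side (median Pearson r ≈ 0.5, inside
  the observed 0.44–0.78 range) and uncorrelated across the midline. It is a
  modelling choice, not a claim about development.
* `d_j` — a per-PN dendrite-size factor. By default d_j = mean(PNs per
  side)/PNs on that side, so the two antennal pools have similar totals and
  individual PNs on the 2-PN side receive ~50% more synapses (and are grown
  with proportionally larger dendrites by `make_bundle`), mirroring the
  observed covariation of dendrite size and synapse load. Pass explicit
  factors (e.g. all ones) for a homogeneous circuit.
* `ε_ij` — i.i.d. lognormal noise with mean 1. Counts are rounded lognormal
  because the source data report only a mean and CV and counts are strictly
  positive and right-skewed.

`base` is calibrated so the expected ipsilateral mean is 26.4
synapses/connection — the value implied by an overall mean of 23 with a 1.35
ipsi/contra ratio at the observed 133/127 split of connection types. The ε
variance is calibrated on the log scale, σ_ε² = ln(1+CV²) − σ_f², so the
total CV of normalized contributions is 0.31; a requested CV below the
latent-factor floor raises an error. Over seeds the generated circuits
recover the surplus, the CV and the correlation structure to within a few
percent.

Synapses are placed uniformly per unit dendritic path length, independently
across ORNs, on dendrite-labelled cables (soma and primary neurite excluded),
and bound to the containing compartment. Per-synapse T-bar volumes and
contact areas are correlated bivariate lognormals with configurable CV
(default 0.5) and log-scale correlation (default 0.5), independent of the
synapse count per connection.

Morphologies grow from a soma through one primary neurite into a binary tree
with exponential inter-branchpoint lengths (default rate 0.02/µm), a fixed
radius taper of 0.88 per branch point from a 0.5 µm root caliber, 5 µm node
spacing and a persistent random-walk direction. Growth stops exactly at the
target path length (default 2000 µm, scaled per PN by d_j); if all tips taper
below 0.05 µm first, generation fails explicitly. These defaults were chosen
once so that the default circuit's ipsilateral uEPSPs average ≈5 mV with
somatic input resistances of several hundred MΩ.

**What the generator does not emulate:** real reconstructed arbors (tuft
geometry, caliber profiles, synapse clustering along axon contacts),
glomerular boundaries and axon trajectories, multiglomerular inputs, gap
junctions or inhibition, and activity-dependent structure. Passing tests on
synthetic circuits therefore validates the machinery and the qualitative
orderings (ipsi > contra, equalized ≥ real decoding, lateralization harder
than detection), not the exact published effect sizes that depend on the real
morphologies — e.g. the shuffle control reproduces the equality of real and
shuffled CVs, but both CVs are larger here than in a real, electrotonically
compact glomerular tuft, and summation efficacies sit near 0.85 rather
than 0.9.

## Resampling and statistics

Permutation tests are two-sided with the add-one rule
`p = (1 + #{|null| ≥ |obs|})/(1 + n_perm)` (never zero), with 10,000
permutations by default; statistics are the difference of means or Pearson's
r (null: permute one variable). Holm's step-down correction is applied to the
same-side correlation family. CVs use the sample SD (n−1). The pooled
ipsi/contra surplus is reported both from grand means over connections and
from averaged per-PN means (the two pooling conventions differ slightly and
both are printed); a paired t-test over PNs accompanies the per-PN version.

The shuffle control permutes the pooled synapse locations of a PN while
preserving each ORN's count; equalization hands each axon floor(N/k) or
floor(N/k)+1 locations drawn without replacement, independently per trial,
per PN–antenna pool (preserving the mean ipsi/contra asymmetry in the
lateralization task).

## Classification tasks

Trials are conditioned Poisson: exactly n spikes uniform on a 200 ms window,
each spike assigned to a uniformly random ORN of the stimulated antenna;
a trial is redrawn whenever any ORN violates a 4 ms refractory interval.
(Assignment is per spike; with exchangeable uniform times a per-train scheme
generates the same trial distribution, so no separate mode is exposed.) The
baseline count of 12 comes from the measured 58 Hz population event rate —
2.2 spikes/s/ORN across 26.5 ORNs — times the 200 ms window.

The decoder is a threshold on a scalar (the optimal linear classifier in one
dimension): detection reads each PN's µ (only ipsilateral ORNs are
simulated, one classifier per PN); lateralization reads mean µ over left PNs
minus mean µ over right PNs while every PN receives both antennae's spikes
through its own synapse map. Thresholds minimize training error (ties broken
toward the midpoint of class means) and are scored on independent held-out
trials.

Per-trial voltages use a linear fast path: the somatic response kernel of a
single synaptic event is precomputed per compartment with the full solver,
and each event contributes its kernel integral `H_c(window − t₀)/window` to
µ. This is exact in the small-conductance limit and neglects the ~10–15%
sublinearity of conductance summation — a common scale factor that does not
move a threshold classifier's accuracy; the full solver remains the reference
and the kernels are themselves full-solver output.

## Problem sizes

Default experiments use 2500 training and 2500 test trials per condition and
10,000 permutations. The test suite and the acceptance script run the same
code at reduced, pre-registered sizes chosen for quick iteration: 250/250
trials, 500-permutation type-I calibration over 1000 replicates, 40–200
generator seeds, and 800–1000 µm task morphologies. All reported quantities
are computed, never stored.

## Known limitations

* No active conductances, spiking PN output, synaptic depression/facilitation
  or inhibitory inputs — the models contain only passive membrane and
  feed-forward ORN→PN synapses.
* The caliber-inflation rule (mean node radius per path) and the soma
  cylinder are conventions; reconstructed data pipelines may average calibers
  differently.
* The linear fast path slightly overstates µ for strong stimuli; accuracy
  orderings are unaffected, absolute µ values at high spike counts are upper
  bounds.
* Synthetic morphologies are statistical stand-ins; quantities tied to real
  arbor geometry (attenuation distributions, efficacy means, shuffle-control
  CVs) should be read as demonstrations of the method.
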