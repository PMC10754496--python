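# Methods

## The model

A single L2/3 pyramidal neuron is represented as a branched tree of
cylindrical compartments plus an isopotential spherical soma. The
membrane carries leak plus seven active conductances — Hodgkin–Huxley
sodium (Na), delayed-rectifier potassium (K_dr), muscarinic potassium
(K_m), A-type potassium (K_A), low-threshold T-type calcium (Ca_T),
high-voltage-activated calcium (Ca_HVA) and calcium-dependent potassium
(K_Ca) — and an intracellular calcium pool fed by the calcium currents
and cleared by a first-order pump (submembrane shell 0.1 µm, decay
200 ms, rest 0.1 µM). Synapses are conductance-based double exponentials
(normalized to peak at g_max): AMPA 0.84 nS (0.1/2.5 ms), NMDA 1.15 nS
(2/30 ms) under the standard sigmoidal magnesium block
1/(1 + [Mg]/3.57 · e^(−0.062 V)) with [Mg] = 1 mM, GABA_A 1.25 nS
(0.2/1.4 ms, reversal −80 mV). An excitatory synapse is a co-located
AMPA+NMDA pair sharing one presynaptic train.

### Passive parameters

C_m = 1 µF/cm², R_a = 100 Ω·cm, g_leak = 1/17300 S/cm² (so the passive
time constant is R_m·C_m = 17.3 ms), e_leak = −79 mV (the passive
resting potential). Reversals: e_Na = +60 mV, e_K = −80 mV,
e_Ca = +140 mV. All are config-exposed and echoed in every output.

### Conductance-density rules and unit reconciliation

Densities depend on region (soma/apical/basal), path distance x (µm,
soma center to segment midpoint) and segment mean diameter d (µm); the
apical Ca_T/Ca_HVA profiles are sinusoids in x (radians) with a plateau
beyond 260 µm, the basal ones linear in x, and K_A switches 108 →
10.8 mS/cm² at d = 0.8 µm. Two facts about the published table required
explicit decisions:

- The sinusoid 0.029·sin(0.009x + 0.88) crosses zero at x ≈ 251.3 µm and
  is negative on (251.3, 260]. Because a conductance density cannot be
  negative, the rule is clamped at zero there; the resulting step at
  x = 260 µm (0 → 0.012 mS/cm²) is reported by the density audit, not
  smoothed away.
- The table's rows mix unit conventions: its K_A figures are classical
  mS/cm² A-current densities, while its Na row (0.505 soma / 0.303
  dendrite) can only support the validated action potentials if read in
  S/cm². `DensityRuleSet.unit_scale` therefore maps each channel's
  published figure onto the simulator's mS/cm² scale (×1000 for Na, K_dr,
  K_m, Ca_HVA, K_Ca; ×1 for K_A and Ca_T). This is a uniform per-row
  reconciliation; the published *relative* anomalies (dendritic K_dr 30×
  below somatic) are kept as printed. `conductance_at` always returns the
  published figures unscaled for auditability.

### Channel kinetics (non-reproduction mode)

The original cell's mechanism files are deposited externally and are not
bundled; the package ships its own documented standard kinetics set:
Mainen & Sejnowski (1996)-style Na/K_dr/K_m/Ca_HVA/K_Ca rate functions, a
Destexhe-type T-current, and a Migliore-style A-current, with no
temperature corrections. The sodium activation midpoint is set 10 mV
depolarized relative to the textbook value, which places somatic spike
threshold near −45 mV and dendritic sodium-spike thresholds at ~5–20
synchronous synapses — the operating regime of the cell class. Runs made
with this set are *non-reproduction mode*: quantitatively they describe
this package's model, not the deposited one.

## Numerics

Each dendritic segment is discretized into compartments no longer than
0.1·λ (config-exposed). Voltage advances by first-order implicit
(backward Euler) steps at dt = 0.1 ms: ionic and synaptic conductances
are frozen at their start-of-step gating values, making the membrane
equation linear in V, and the branched-tree linear system is solved
exactly each step by Hines elimination (O(n), parents ordered before
children). Gates follow the exact exponential update
x ← x∞ + (x − x∞)e^(−dt/τ), unconditionally stable and confined to
[0, 1] for any dt; synaptic states use the analogous two-state exact
decay with unit increments per delivered event, so superposition is
exact. The NMDA block factor is evaluated at the previous step's voltage.
Calcium relaxes exponentially toward rest plus the influx steady state
within each step. Accuracy is quantified by tests rather than assumed:
steady-state cable attenuation matches cosh(L) within 1%, the passive τ
and R_in within 0.5%, somatic spike times move < 0.1 ms under dt
halving, and grid refinement changes steady responses < 1%.

Somatic spikes are upward crossings of 0 mV separated by ≥ 3 ms, with
sub-sample linear interpolation. Runs are bit-reproducible given
identical inputs and seeds; every protocol derives its randomness from a
single master seed via spawned substreams (one per synapse for event
trains).

## Synthetic cell and study conditions

The synthetic morphology generator emulates the cell class's anatomy:
seven basal stems (60–100 µm, 1.3–1.8 µm diameter, occasionally
bifurcating) sprouting from the soma, and one apical trunk (180 µm,
1.8 µm) opening into a depth-4 binary tuft (~60 µm, ~1 µm segments,
mild taper). With these defaults most basal segments lie below the
182.7 µm path-distance split while most of the tuft lies beyond it, and
the soma's current-sink effect gives basal segments higher sodium-spike
thresholds than apical segments of similar electrotonic length — the two
anatomical asymmetries the attribution results hinge on.

Tuned-input runs use the published study conditions: 2500 ms runs with
stimulus onset at 500 ms, background synapses 75% of the population at
0.11 Hz, stimulus-driven 25% at up to 0.3 Hz, stimulus-driven apical
synapses delayed 10 ms, per-synapse preferences Gaussian (σ = 30°) around
each tree's mean, and rate tuning Gaussian in circular orientation
distance (σ = 30°, config-exposed). Two population parameters are not
published and were fixed once at values that put the model in the
reported operating regime (preferred-orientation rate ≈ 1.5 Hz,
orthogonal ≈ 0.2–0.6 Hz): the total synapse count (7200 across ~2.9 mm
of dendrite, ≈ 2.5 synapses/µm) and the inhibitory share of the
background pool (20%). Inhibition is background-driven only, untuned,
with 7% of GABA_A contacts on the soma and the rest split across the
trees per the distribution model.

What passing synthetic-cell tests establish: the machinery — allocation,
event generation, integration, interventions, metrics — behaves
correctly, and the qualitative phenomena (supralinear dendrites,
orientation tuning that collapses without tuned drive, apical-dominant
spike attribution, distance-dominated apical attenuation) emerge from
the same physics as in the original cell. What they do not establish:
the original cell's exact figures, which depend on the deposited
reconstruction and mechanism set; reproducing those requires the
one-time ModelDB 267501 download and hoc→SWC conversion described in the
README.

## Protocol details and open choices

- **I3P**: each tested segment keeps its active conductances while every
  other compartment (soma included) is passive; n synapses at the segment
  midpoint fire two synchronous volleys 20 ms apart (50 Hz) in a 700 ms
  window with onset at 100 ms; the first volley's local peak builds the
  input-output curve. The dendritic-spike criterion (default: ≥ 20 mV
  above baseline AND ≥ 10 mV/ms) applies its slope gate only from 1 ms
  after the volley, so that arbitrarily large *passive* EPSPs — whose
  fast rise is purely synaptic — are never counted as spikes; only
  responses still rising after the AMPA conductance has peaked qualify
  as regenerative. NRLE = max over n ≥ 2 of actual(n)/(n·actual(1)). A
  current-pulse drive mode provides an exactly linear control (NRLE = 1)
  validating the measurement path.
- **Tuning**: each trial is one model instance (fresh preference draw +
  fresh trains) run at every orientation; rate = spikes in
  [onset, end] / window. Metrics are computed per trial and averaged
  (mean ± SEM), with the metrics of the mean curve also reported. Tuning
  width is the σ of the wrapped-Gaussian fit, not HWHM; the choice is
  recorded in output metadata. OSI uses the curve interpolated at the
  fitted preferred and preferred + 90°.
- **Disparity**: apical preferences mean 0°, basal mean D ∈ {0,…,90°};
  the linear expectation is ½·arg(w_a + w_b·e^(i2D)) with count weights;
  a configuration is inadequately tuned when ≥ 20% of instances have
  OSI < 0.2 or width > 80°.
- **Interventions**: windows are closed intervals locked to each
  pre-recorded baseline spike (ionic: g_Na × 0 on one tree, −3/+1 ms;
  synaptic: stimulus-driven AMPA/NMDA weights × 0.5, −30/+10 ms); scaling
  acts on conductance/weights only — gates keep evolving. A spike
  survives if the replayed run fires within ±5 ms of it. Replay uses the
  identical event list, so a null intervention reproduces the baseline
  exactly, and the four classes partition the baseline spikes by
  construction.
- **Attenuation**: EPSP mode runs on the fully passive membrane
  (a ~20 mV local depolarization would otherwise ignite the probed
  segment), bisecting the synaptic weight until the local peak is within
  ±1 mV of 20 mV; spike mode keeps the probed segment active (I3P-style)
  and escalates drive past its sodium threshold. Attenuation is the
  difference of local and somatic peak depolarizations in mV.
- **Ablation**: removes all apical compartments and synapses; the
  homeostatic variant scales the remaining excitatory weights by
  bisection until the preferred-orientation rate matches the intact
  model within 10%, mimicking the compensation that keeps firing rates
  stable after dendrotomy in vivo.
- **Sensitivity**: whole-run apical g_Na scaling (1.0/0.95/0.90) re-runs
  the intervention protocol per scale.

## Known limitations

- The kinetics set, reversal potentials and calcium parameters are this
  package's own (documented above); absolute voltages, thresholds and
  rates differ from the deposited model even at matched densities.
- The synthetic cell is one stylized morphology; per-segment numbers
  (thresholds, NRLE, attenuation) vary with its geometry and should be
  read as class-typical, not cell-specific.
- Poisson drive is stationary and independent across synapses; no
  interneuron patterning, short-term plasticity, or retinotopic
  structure.
- Spike counts at the study's physiological rates are small (a few per
  2 s window), so per-trial percentages and metrics carry the
  corresponding sampling noise; SEMs are reported throughout.
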