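"""Attribute each somatic spike to its dendritic origin (one trial).

For every baseline spike, the identical Poisson events are replayed
twice with sodium conductance nullified on one tree for the 4 ms around
the spike. A spike lost only under the apical nullification is apically
driven, only under basal is basally driven, under both cooperative, and
under neither independent.
"""

from dendrosynergy import DensityRuleSet, PassiveParams, SimConfig, \
    generate_spike_trains, generate_synthetic_morphology
from dendrosynergy.protocols import ModelConfig, build_model, \
    intervention_trial

m = generate_synthetic_morphology()
mc = ModelConfig()
system = build_model(m, mc, PassiveParams(), DensityRuleSet(), seed=42)
cfg = SimConfig(duration=1500.0)
trains = generate_spike_trains(system.synapses, mc.stimulus(0.0, 500.0),
                               cfg.duration, seed=77)

trial = intervention_trial(system, cfg, trains, "ionic")
print(f"baseline spikes: {trial.n_spikes}")
for o in trial.outcomes:
    print(f"  t = {o.spike_time:7.1f} ms -> {o.label}")
print({k: f"{v:.0f}%" for k, v in trial.percentages.items()})
print("\nMost spikes depend on apical sodium conductance even though "
      "60% of the tuned input lands on the basal tree — the apical tree "
      "drives spiking, the basal tree gates it.")
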