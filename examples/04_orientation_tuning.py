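"""Measure the model's orientation tuning curve (reduced run).

Stimulus-driven synapses fire as Poisson processes whose rate is a
Gaussian function of the angular distance between their preference and
the stimulus; background synapses fire untuned at 0.11 Hz throughout.
The somatic spike rate per orientation yields OSI, width and preference.
"""

from dendrosynergy import SimConfig, generate_synthetic_morphology
from dendrosynergy.protocols import ModelConfig, tuning_experiment

m = generate_synthetic_morphology()
res = tuning_experiment(m, ModelConfig(), SimConfig(),
                        orientations=range(0, 180, 30), n_trials=2, seed=5)

for th, r, s in zip(res.curve.orientations, res.curve.mean_rate,
                    res.curve.sem_rate):
    print(f"  {th:5.0f} deg  {r:.2f} +/- {s:.2f} Hz")
mm = res.metrics_mean_curve
print(f"\nOSI = {mm.osi:.2f}, width = {mm.width:.1f} deg, "
      f"preferred = {mm.preferred:.1f} deg")
print("An OSI above 0.2 with width below 80 deg marks the neuron as "
      "well tuned; the preference tracks the 0-deg mean of the synaptic "
      "preference distributions.")
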