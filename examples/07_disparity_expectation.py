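"""Linear (Euler-formula) expectation of somatic preference under
apical/basal tuning disparity.

When the apical tree is tuned to 0 deg and the basal tree to D, linear
summation predicts a somatic preference at half the argument of the
weighted resultant of doubled angles. Measured preferences that deviate
toward one tree reveal that tree's dominance.
"""

from dendrosynergy import DISTRIBUTION_MODELS, expected_preference_euler

for name in ("biologically_plausible", "even", "inverted"):
    model = DISTRIBUTION_MODELS[name]
    row = []
    for D in (0.0, 20.0, 40.0, 60.0, 90.0):
        pref, _ = expected_preference_euler(
            [0.0, D], [model.apical_fraction_stim,
                       model.basal_fraction_stim])
        row.append("undef" if pref is None else f"{pref:5.1f}")
    print(f"{name:24s} D=0,20,40,60,90 -> {row}")

print("\nWith 60% of tuned synapses basal, the linear expectation leans "
      "toward the basal mean; the simulated neuron leans even further — "
      "the signature of nonlinear basal dominance in preference.")
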