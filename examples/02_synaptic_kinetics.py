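"""Closed-form properties of the three synaptic conductances.

Each synapse is a double exponential g(t) = g_max N (e^{-t/tau2} -
e^{-t/tau1}) normalized to peak at g_max; NMDA is additionally gated by
the voltage-dependent magnesium block.
"""

from dendrosynergy import KINETICS, mg_block, synaptic_conductance

for name, kin in KINETICS.items():
    tp = kin.time_to_peak
    print(f"{name:7s} tau1={kin.tau1:4.1f} ms tau2={kin.tau2:4.1f} ms "
          f"time-to-peak={tp:5.3f} ms peak={synaptic_conductance(kin, tp):.3f} nS "
          f"reversal={kin.reversal:+.0f} mV")

print(f"\nNMDA magnesium unblock: {mg_block(-80.0):.3f} at -80 mV vs "
      f"{mg_block(40.0):.3f} at +40 mV — the voltage dependence that "
      "makes NMDA a coincidence detector.")
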