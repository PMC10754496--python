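import math

import numpy as np
import pytest

from dendrosynergy import (CurrentClamp, DensityRuleSet, EventTrain,
                           InterventionSpec, Morphology, PassiveParams,
                           Segment, SimConfig, SimulationError, SynapseSpec,
                           System, detect_somatic_spikes, run,
                           space_constant)


def cylinder_system(length=500.0, diameter=1.0, passive=None,
                    lambda_fraction=0.02):
    """Tiny soma + one uniform dendritic cylinder, fully passive."""
    passive = passive or PassiveParams()
    segs = {0: Segment(0, -1, "soma", 1e-3, 1e-3, 0.0, 0),
            1: Segment(1, 0, "basal", length, diameter, length / 2, 0)}
    return System(Morphology(segs), passive,
                  DensityRuleSet().passive_copy(), [],
                  lambda_fraction=lambda_fraction)


def sphere_system(diameter=20.0, passive=None):
    passive = passive or PassiveParams()
    segs = {0: Segment(0, -1, "soma", diameter, diameter, 0.0, 0)}
    return System(Morphology(segs), passive,
                  DensityRuleSet().passive_copy(), [])


class TestCompartmentalization:
    def test_passive_sphere_is_single_compartment(self):
        assert sphere_system().n_comp == 1

    def test_ceiling_rule_on_uniform_cylinder(self):
        # lambda = 500 um (R_m = 10 kOhm cm^2, d = 1 um, R_a = 100 Ohm cm)
        passive = PassiveParams(g_leak=1e-4)
        sys_ = cylinder_system(500.0, 1.0, passive, lambda_fraction=0.1)
        assert sys_.n_comp == 1 + 10  # soma + ceil(L / 0.1 lambda)

    def test_max_compartment_guard(self):
        passive = PassiveParams()
        segs = {0: Segment(0, -1, "soma", 10.0, 10.0, 0.0, 0),
                1: Segment(1, 0, "basal", 5000.0, 1.0, 2500.0, 0)}
        with pytest.raises(SimulationError, match="compartments"):
            System(Morphology(segs), passive, DensityRuleSet(), [],
                   lambda_fraction=0.001, max_compartments=50)

    def test_grid_refinement_converges(self):
        passive = PassiveParams()
        cfg = SimConfig(dt=0.1, duration=300.0, stimulus_onset=0.0)
        vals = []
        for frac in (0.05, 0.025):
            sys_ = cylinder_system(400.0, 1.0, passive, lambda_fraction=frac)
            res = run(sys_, cfg, clamps=[CurrentClamp(1, 0.05, 0.0, 300.0)])
            vals.append(res.traces[0][-1])
        assert abs(vals[1] - vals[0]) / abs(vals[0] + 79.0) < 0.01


class TestPassiveOracles:
    def test_flat_trace_at_leak_reversal_with_zero_input(self):
        sys_ = sphere_system()
        cfg = SimConfig(dt=0.1, duration=100.0, stimulus_onset=0.0)
        res = run(sys_, cfg)
        np.testing.assert_allclose(res.traces[0], -79.0, atol=1e-9)

    def test_sealed_cable_attenuation_matches_cosh(self):
        # steady current into the proximal end of a sealed cylinder:
        # V(0)/V(l) = cosh(L_e) from the finite-cable solution
        passive = PassiveParams()
        sys_ = cylinder_system(500.0, 1.0, passive)
        lam = space_constant(1.0, passive)
        L = 500.0 / lam
        cfg = SimConfig(dt=0.1, duration=400.0, stimulus_onset=0.0)
        res = run(sys_, cfg, clamps=[CurrentClamp(0, 0.01, 0.0, 400.0)],
                  record_segments=[0, 1])
        dv0 = res.traces[0][-1] + 79.0
        dv_mid = res.traces[1][-1] + 79.0
        assert dv0 / dv_mid == pytest.approx(
            math.cosh(L) / math.cosh(L / 2), rel=0.01)

    def test_sphere_input_resistance_and_time_constant(self):
        passive = PassiveParams()
        d = 20.0
        sys_ = sphere_system(d, passive)
        area = math.pi * (d * 1e-4) ** 2
        rin_mohm = passive.r_m / area / 1e6
        cfg = SimConfig(dt=0.025, duration=200.0, stimulus_onset=0.0)
        res = run(sys_, cfg, clamps=[CurrentClamp(0, -0.04, 0.0, 200.0)])
        v = res.traces[0]
        dv = v[-1] + 79.0
        assert dv / (-0.04) == pytest.approx(rin_mohm, rel=0.005)
        # exponential approach with tau = R_m C_m = 17.3 ms
        t = res.times
        frac = (v - v[-1]) / (v[0] - v[-1])
        mask = (frac > 0.05) & (frac < 0.95)
        tau_fit = -1.0 / np.polyfit(t[mask], np.log(frac[mask]), 1)[0]
        assert tau_fit == pytest.approx(17.3, rel=0.005)


@pytest.fixture(scope="module")
def driven(morphology, passive, rules):
    specs = [SynapseSpec(j, sid, "exc", "background", 0.5)
             for j, sid in enumerate(
                 [s.segment_id
                  for s in morphology.dendritic_segments()][:20])]
    system = System(morphology, passive, rules, specs)
    rng = np.random.default_rng(0)
    trains = [EventTrain(j, np.sort(rng.uniform(0, 900, 12)))
              for j in range(len(specs))]
    cfg = SimConfig(dt=0.1, duration=1000.0, stimulus_onset=0.0)
    return system, cfg, trains


class TestReproducibilityAndInterventions:
    def test_bit_reproducible(self, driven):
        system, cfg, trains = driven
        a = run(system, cfg, trains=trains)
        b = run(system, cfg, trains=trains)
        np.testing.assert_array_equal(a.traces, b.traces)
        np.testing.assert_array_equal(a.somatic_spike_times,
                                      b.somatic_spike_times)

    def test_unit_scale_intervention_is_identity(self, driven):
        system, cfg, trains = driven
        a = run(system, cfg, trains=trains)
        b = run(system, cfg, trains=trains, interventions=[
            InterventionSpec("apical", "g_Na", 1.0, 100.0, 900.0),
            InterventionSpec("basal", "stim_syn_weight", 1.0, 0.0, 1000.0)])
        np.testing.assert_array_equal(a.traces, b.traces)

    def test_window_outside_run_rejected(self, driven):
        system, cfg, trains = driven
        with pytest.raises(SimulationError):
            run(system, cfg, interventions=[
                InterventionSpec("apical", "g_Na", 0.0, 2000.0, 3000.0)])

    def test_whole_run_window_equals_built_in_block(self, driven):
        system, cfg, trains = driven
        via_window = run(system, cfg, trains=trains, interventions=[
            InterventionSpec("apical", "g_Na", 0.0, 0.0, cfg.duration)])
        via_rules = run(system.sodium_block("apical"), cfg, trains=trains)
        np.testing.assert_allclose(via_window.traces, via_rules.traces,
                                   atol=1e-9)

    def test_halving_dt_keeps_spike_times(self, morphology, passive, rules):
        # convergence: spike times move < 0.1 ms under dt refinement
        segs = [s.segment_id for s in morphology.dendritic_segments()][:10]
        specs = [SynapseSpec(j, sid, "exc", "background", 0.5,
                             weight_scale=30.0)
                 for j, sid in enumerate(segs)]
        system = System(morphology, passive, rules, specs)
        trains = [EventTrain(j, np.array([50.0])) for j in range(len(specs))]
        times = {}
        for dt in (0.1, 0.05):
            cfg = SimConfig(dt=dt, duration=200.0, stimulus_onset=0.0)
            res = run(system, cfg, trains=trains)
            times[dt] = res.somatic_spike_times
        assert len(times[0.1]) == len(times[0.05]) >= 1
        np.testing.assert_allclose(times[0.1], times[0.05], atol=0.1)


class TestSpikeDetection:
    def test_flat_trace_no_spikes(self):
        assert detect_somatic_spikes(np.full(1000, -79.0), 0.1).size == 0

    def test_three_separated_transients(self):
        t = np.arange(0, 300, 0.1)
        v = np.full_like(t, -79.0)
        for t0 in (50, 150, 250):
            v += 50.0 * np.exp(-((t - t0) ** 2) / 2.0)
        spikes = detect_somatic_spikes(v, 0.1, threshold=-40.0)
        assert spikes.size == 3
        np.testing.assert_allclose(spikes, [50, 150, 250], atol=2.0)

    def test_refractory_merges_close_crossings(self):
        t = np.arange(0, 20, 0.1)
        v = np.full_like(t, -79.0)
        for t0 in (5.0, 6.0):
            v += 90.0 * np.exp(-((t - t0) ** 2) / 0.02)
        assert detect_somatic_spikes(v, 0.1, threshold=0.0,
                                     refractory=3.0).size == 1
        assert detect_somatic_spikes(v, 0.1, threshold=0.0,
                                     refractory=0.5).size == 2

    def test_subsample_interpolation(self):
        v = np.array([-10.0, -2.0, 6.0, 10.0])
        t = detect_somatic_spikes(v, 1.0, threshold=0.0)
        assert t == pytest.approx([1.25])
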