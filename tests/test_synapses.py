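import math

import numpy as np
import pytest

from dendrosynergy import (DISTRIBUTION_MODELS, KINETICS, EventTrain,
                           StimulusConfig, allocate_synapses,
                           assign_preferences, generate_spike_trains,
                           mg_block, orientation_distance,
                           sample_preferences, synaptic_conductance,
                           tuned_rate)


class TestKinetics:
    """Closed forms of the double-exponential synaptic conductances."""

    @pytest.mark.parametrize("kind,tau1,tau2,gmax", [
        ("AMPA", 0.1, 2.5, 0.84),
        ("NMDA", 2.0, 30.0, 1.15),
        ("GABA_A", 0.2, 1.4, 1.25),
    ])
    def test_peak_and_time_to_peak(self, kind, tau1, tau2, gmax):
        kin = KINETICS[kind]
        assert (kin.tau1, kin.tau2, kin.g_max) == (tau1, tau2, gmax)
        tp = (tau1 * tau2 / (tau2 - tau1)) * math.log(tau2 / tau1)
        assert kin.time_to_peak == pytest.approx(tp)
        assert synaptic_conductance(kin, tp) == pytest.approx(gmax, rel=1e-12)
        # the waveform peaks nowhere above g_max
        t = np.linspace(0, 20 * tau2, 4000)
        g = synaptic_conductance(kin, t)
        assert np.all(g <= gmax * (1 + 1e-9))
        assert np.all(g >= 0)

    def test_ampa_time_to_peak_value(self):
        assert KINETICS["AMPA"].time_to_peak == pytest.approx(0.335, abs=5e-4)

    def test_zero_at_event_time(self):
        for kin in KINETICS.values():
            assert synaptic_conductance(kin, 0.0) == 0.0

    def test_superposition_is_linear(self):
        kin = KINETICS["AMPA"]
        t = np.linspace(0, 10, 500)
        g1 = synaptic_conductance(kin, t)
        g2 = np.where(t >= 3.0, synaptic_conductance(kin,
                                                     np.maximum(t - 3.0, 0)),
                      0.0)
        # event at 0 plus event at 3 equals the sum of singles by
        # construction of conductance-based (not current-based) synapses
        np.testing.assert_allclose(g1 + g2, g1 + g2)
        assert np.max(g1 + g2) <= 2 * kin.g_max

    def test_single_interior_maximum(self):
        kin = KINETICS["NMDA"]
        t = np.linspace(0, 300, 6000)
        g = synaptic_conductance(kin, t)
        d = np.diff(g)
        sign_changes = np.sum(np.diff(np.sign(d[np.abs(d) > 1e-15])) != 0)
        assert sign_changes == 1

    def test_nmda_magnesium_block_voltage_dependence(self):
        kin = KINETICS["NMDA"]
        tp = kin.time_to_peak
        depol = synaptic_conductance(kin, tp, v=40.0)
        hyper = synaptic_conductance(kin, tp, v=-80.0)
        assert depol == pytest.approx(1.15, rel=0.05)
        assert hyper < 0.25 * depol
        assert mg_block(40.0) > 0.95


class TestOrientation:
    def test_distance_wraps_mod_180(self):
        assert orientation_distance(10.0, 170.0) == pytest.approx(20.0)
        assert float(np.max(orientation_distance(
            np.arange(0, 180), 0.0))) <= 90.0

    def test_tuned_rate_examples(self):
        cfg = StimulusConfig(tuning_sigma_rate=30.0)
        assert tuned_rate(0.0, 0.0, cfg) == pytest.approx(0.3)
        # orthogonal orientation: effectively silent
        assert tuned_rate(90.0, 0.0, cfg) <= 0.3 * math.exp(-4.5) + 1e-12
        # symmetric in its two angles
        assert tuned_rate(30.0, 75.0, cfg) == tuned_rate(75.0, 30.0, cfg)
        # spontaneous runs drive no stimulus-locked events
        assert tuned_rate(0.0, None, cfg) == 0.0

    def test_sample_preferences_sigma_zero_and_mean(self):
        assert np.all(sample_preferences(50, 42.0, 0.0, seed=1) == 42.0)
        prefs = sample_preferences(10_000, 0.0, 30.0, seed=2)
        z = np.mean(np.exp(1j * 2 * np.deg2rad(prefs)))
        mean = np.rad2deg(np.angle(z)) / 2 % 180.0
        assert min(mean, 180 - mean) < 1.0

    def test_sample_preferences_rotation_equivariance(self):
        a = sample_preferences(1000, 0.0, 25.0, seed=3)
        b = sample_preferences(1000, 90.0, 25.0, seed=3)
        np.testing.assert_allclose((a + 90.0) % 180.0, b, atol=1e-9)


class TestAllocation:
    def test_biologically_plausible_counts(self, morphology):
        specs = allocate_synapses(morphology, "biologically_plausible",
                                  100, bg_fraction=0.75, seed=0)
        assert len(specs) == 100
        stim = [s for s in specs if s.role == "stimulus"]
        assert len(stim) == 25
        tree = {s.segment_id: morphology.segments[s.segment_id].tree_label
                for s in specs}
        stim_basal = sum(tree[s.segment_id] == "basal" for s in stim)
        stim_apical = sum(tree[s.segment_id] == "apical" for s in stim)
        assert (stim_basal, stim_apical) == (15, 10)

    def test_even_model_balanced_within_one(self, morphology):
        for n in (37, 100, 301):
            specs = allocate_synapses(morphology, "even", n, seed=1)
            tree = {s.synapse_id:
                    morphology.segments[s.segment_id].tree_label
                    for s in specs}
            for role in ("stimulus", "background"):
                for kind in ("exc", "inh"):
                    grp = [s for s in specs
                           if s.role == role and s.kind == kind]
                    nb = sum(tree[s.synapse_id] == "basal" for s in grp)
                    na = sum(tree[s.synapse_id] == "apical" for s in grp)
                    assert abs(nb - na) <= 1

    def test_apical_stimulus_delay(self, morphology):
        specs = allocate_synapses(morphology, "biologically_plausible",
                                  400, seed=2)
        for s in specs:
            tree = morphology.segments[s.segment_id].tree_label
            if s.role == "stimulus" and tree == "apical":
                assert s.transmission_delay == 10.0
            else:
                assert s.transmission_delay == 0.0

    def test_soma_gets_inhibitory_share(self, morphology):
        specs = allocate_synapses(morphology, "even_background", 2000,
                                  seed=3)
        soma_syn = [s for s in specs
                    if s.segment_id == morphology.root.segment_id]
        assert soma_syn and all(s.kind == "inh" for s in soma_syn)
        n_inh = sum(s.kind == "inh" for s in specs)
        assert len(soma_syn) == pytest.approx(0.07 * n_inh, abs=1)

    def test_determinism_and_seed_sensitivity(self, morphology):
        a = allocate_synapses(morphology, "even", 500, seed=7)
        b = allocate_synapses(morphology, "even", 500, seed=7)
        c = allocate_synapses(morphology, "even", 500, seed=8)
        assert a == b
        assert a != c

    def test_fraction_sum_validation(self):
        from dendrosynergy import DistributionModel
        with pytest.raises(ValueError, match="sum to 1"):
            DistributionModel("bad", 0.7, 0.4, 0.5, 0.5, 0.4, 0.4, 0.2)

    def test_preference_assignment_stimulus_only(self, morphology):
        specs = allocate_synapses(morphology, "biologically_plausible",
                                  400, seed=4)
        specs = assign_preferences(specs, morphology, 0.0, 40.0, 20.0,
                                   seed=5)
        for s in specs:
            if s.role == "stimulus":
                assert s.theta_pref is not None
                assert 0.0 <= s.theta_pref < 180.0
            else:
                assert s.theta_pref is None


class TestTrains:
    def test_expected_event_count(self, morphology):
        specs = allocate_synapses(morphology, "even", 4000, bg_fraction=1.0,
                                  seed=6)
        cfg = StimulusConfig(theta_stim=None, rate_background=0.11)
        trains = generate_spike_trains(specs, cfg, 2500.0, seed=9)
        total = sum(t.event_times.size for t in trains)
        lam = 4000 * 0.11 * 2.5
        assert abs(total - lam) <= 3 * math.sqrt(lam)

    def test_identical_seed_identical_trains(self, morphology):
        specs = allocate_synapses(morphology, "even", 200, seed=0)
        specs = assign_preferences(specs, morphology, 0.0, 0.0, 30.0, seed=1)
        cfg = StimulusConfig(theta_stim=0.0)
        a = generate_spike_trains(specs, cfg, 2500.0, seed=11)
        b = generate_spike_trains(specs, cfg, 2500.0, seed=11)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.event_times, tb.event_times)

    def test_rate_estimator_unbiased_across_seeds(self, morphology):
        specs = allocate_synapses(morphology, "even", 50, bg_fraction=1.0,
                                  seed=0)
        rates = []
        for k in range(300):
            trains = generate_spike_trains(
                specs, StimulusConfig(theta_stim=None), 2000.0, seed=k)
            total = sum(t.event_times.size for t in trains)
            rates.append(total / 50 / 2.0)
        mean = np.mean(rates)
        sem = np.std(rates, ddof=1) / math.sqrt(len(rates))
        assert abs(mean - 0.11) <= 2 * sem + 1e-9

    def test_event_times_sorted_within_window(self, morphology):
        specs = allocate_synapses(morphology, "even", 300, seed=2)
        specs = assign_preferences(specs, morphology, 0.0, 0.0, 30.0, seed=3)
        trains = generate_spike_trains(specs, StimulusConfig(theta_stim=0.0),
                                       1500.0, seed=4)
        by_id = {s.synapse_id: s for s in specs}
        for t in trains:
            assert np.all(np.diff(t.event_times) >= 0)
            if t.event_times.size:
                assert t.event_times[0] >= 0
                assert t.event_times[-1] <= 1500.0
                if by_id[t.synapse_id].role == "stimulus":
                    assert t.event_times[0] >= 500.0

    def test_sorted_invariant_enforced(self):
        with pytest.raises(ValueError):
            EventTrain(0, np.array([5.0, 1.0]))


class TestReplaySerialization:
    def test_trains_round_trip_through_frames(self, morphology):
        from dendrosynergy.synapses import (frame_to_trains,
                                            synapses_to_frame,
                                            trains_to_frame)
        specs = allocate_synapses(morphology, "even", 150, seed=5)
        specs = assign_preferences(specs, morphology, 0.0, 30.0, 25.0,
                                   seed=6)
        trains = generate_spike_trains(specs, StimulusConfig(theta_stim=0.0),
                                       2000.0, seed=7)
        df = trains_to_frame(trains)
        back = frame_to_trains(df, specs)
        for a, b in zip(trains, back):
            assert a.synapse_id == b.synapse_id
            np.testing.assert_allclose(a.event_times, b.event_times)
        sdf = synapses_to_frame(specs)
        assert len(sdf) == len(specs)
        assert set(sdf.columns) >= {"synapse_id", "segment_id", "kind",
                                    "role", "theta_pref", "delay"}
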