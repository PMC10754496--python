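"""Synaptic drive: kinetics, allocation across trees, and Poisson trains.

Synapse accounting follows the source model's convention: an *excitatory
synapse* is a co-located AMPA+NMDA pair sharing one presynaptic event
train; an *inhibitory synapse* is a single GABA_A contact. Stimulus-driven
synapses are excitatory and orientation-tuned; background synapses
(excitatory and inhibitory) fire untuned at a low rate for the whole run.
Apical stimulus-driven synapses carry a 10 ms transmission delay,
reflecting the longer feedback pathway they model.

Orientation arithmetic is everywhere modulo 180 deg with circular
distances <= 90 deg; interfaces use degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .morphology import Morphology

APICAL_STIM_DELAY_MS = 10.0


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynapseKinetics:
    """Double-exponential conductance: g(t) = g_max N (e^{-t/tau2} - e^{-t/tau1})."""
    kind: str
    g_max: float   # nS (peak)
    tau1: float    # ms rise
    tau2: float    # ms decay
    reversal: float  # mV

    def __post_init__(self) -> None:
        if not (self.tau2 > self.tau1 > 0):
            raise ValueError("need tau2 > tau1 > 0")
        if self.g_max <= 0:
            raise ValueError("g_max must be positive")

    @property
    def time_to_peak(self) -> float:
        t1, t2 = self.tau1, self.tau2
        return (t1 * t2 / (t2 - t1)) * math.log(t2 / t1)

    @property
    def norm_factor(self) -> float:
        tp = self.time_to_peak
        return 1.0 / (math.exp(-tp / self.tau2) - math.exp(-tp / self.tau1))


KINETICS = {
    "NMDA": SynapseKinetics("NMDA", 1.15, 2.0, 30.0, 0.0),
    "AMPA": SynapseKinetics("AMPA", 0.84, 0.1, 2.5, 0.0),
    "GABA_A": SynapseKinetics("GABA_A", 1.25, 0.2, 1.4, -80.0),
}

MG_CONCENTRATION_MM = 1.0


def mg_block_params(mg: float = MG_CONCENTRATION_MM) -> tuple[float, float]:
    """(eta, gamma) of the sigmoidal NMDA magnesium unblock factor
    1 / (1 + eta * exp(-gamma V)); standard Jahr-Stevens form."""
    return mg / 3.57, 0.062


def mg_block(v: float, mg: float = MG_CONCENTRATION_MM) -> float:
    eta, gamma = mg_block_params(mg)
    return 1.0 / (1.0 + eta * math.exp(-gamma * v))


def synaptic_conductance(kinetics: SynapseKinetics, t_since_event,
                         v: float | None = None) -> np.ndarray | float:
    """Single-event conductance in nS at time(s) since the event; the NMDA
    variant is multiplied by the magnesium unblock factor when v given."""
    t = np.asarray(t_since_event, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_event must be >= 0")
    g = kinetics.g_max * kinetics.norm_factor * (
        np.exp(-t / kinetics.tau2) - np.exp(-t / kinetics.tau1))
    if kinetics.kind == "NMDA" and v is not None:
        g = g * mg_block(v)
    return g if g.ndim else float(g)


# ---------------------------------------------------------------------------
# Specs and distribution models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynapseSpec:
    synapse_id: int
    segment_id: int
    kind: str                    # 'exc' (AMPA+NMDA pair) | 'inh' (GABA_A)
    role: str                    # 'stimulus' | 'background'
    pos: float = 0.5             # location along the segment, 0..1
    theta_pref: float | None = None  # degrees in [0, 180), stimulus only
    weight_scale: float = 1.0
    transmission_delay: float = 0.0

    def with_weight(self, w: float) -> "SynapseSpec":
        return replace(self, weight_scale=w)

    def with_pref(self, theta: float) -> "SynapseSpec":
        return replace(self, theta_pref=theta)


@dataclass(frozen=True)
class DistributionModel:
    """Apical/basal allocation fractions per synapse category.

    Stimulus-driven and background excitatory synapses split between the
    trees; background inhibition additionally has a somatic share.
    """
    name: str
    basal_fraction_stim: float
    apical_fraction_stim: float
    basal_fraction_bg: float
    apical_fraction_bg: float
    basal_fraction_inhib: float
    apical_fraction_inhib: float
    soma_fraction_inhib: float

    def __post_init__(self) -> None:
        for total, what in [
                (self.basal_fraction_stim + self.apical_fraction_stim, "stim"),
                (self.basal_fraction_bg + self.apical_fraction_bg, "background"),
                (self.basal_fraction_inhib + self.apical_fraction_inhib
                 + self.soma_fraction_inhib, "inhibitory")]:
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{what} fractions must sum to 1 (got {total})")


def _inhib_split(basal: float, apical: float,
                 soma: float = 0.07) -> tuple[float, float, float]:
    rest = 1.0 - soma
    return basal * rest, apical * rest, soma


_bp_inh = _inhib_split(0.6, 0.4)
_ev_inh = _inhib_split(0.5, 0.5)
_iv_inh = _inhib_split(0.4, 0.6)

DISTRIBUTION_MODELS = {
    # 60% of tuned input on the basal tree, feedforward-dominated
    "biologically_plausible": DistributionModel(
        "biologically_plausible", 0.6, 0.4, 0.6, 0.4, *_bp_inh),
    "even": DistributionModel("even", 0.5, 0.5, 0.5, 0.5, *_ev_inh),
    "inverted": DistributionModel("inverted", 0.4, 0.6, 0.4, 0.6, *_iv_inh),
    # alias used by the intervention case studies (case #1/#2)
    "control_background": DistributionModel(
        "control_background", 0.6, 0.4, 0.6, 0.4, *_bp_inh),
    # stimulus-driven synapses stay 60/40 but the background is equalized
    # (case #3/#4): inhibitory 46.5/46.5/7
    "even_background": DistributionModel(
        "even_background", 0.6, 0.4, 0.5, 0.5, 0.465, 0.465, 0.07),
}


@dataclass(frozen=True)
class StimulusConfig:
    """Stimulus and rate parameters for one run."""
    theta_stim: float | None = 0.0   # degrees; None = spontaneous
    onset: float = 500.0             # ms
    rate_stim_peak: float = 0.3      # Hz at zero orientation offset
    rate_background: float = 0.11    # Hz, whole run
    tuning_sigma_rate: float = 30.0  # deg, width of the rate tuning

    def __post_init__(self) -> None:
        if self.rate_stim_peak < 0 or self.rate_background < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class EventTrain:
    synapse_id: int
    event_times: np.ndarray  # ms, sorted

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", t)
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("event times must be sorted")


# ---------------------------------------------------------------------------
# Orientation helpers
# ---------------------------------------------------------------------------

def orientation_distance(a, b):
    """Circular orientation difference in degrees, in [0, 90]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


def sample_preferences(n: int, mean: float, sigma: float,
                       seed) -> np.ndarray:
    """Gaussian orientation preferences wrapped to [0, 180)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    return (rng.normal(mean, sigma, size=n)) % 180.0


def tuned_rate(theta_pref: float, theta_stim: float | None,
               cfg: StimulusConfig) -> float:
    """Stimulus-driven firing rate in Hz: Gaussian in circular orientation
    distance; zero for spontaneous runs."""
    if theta_stim is None:
        return 0.0
    d = float(orientation_distance(theta_pref, theta_stim))
    s = cfg.tuning_sigma_rate
    if s == 0:
        return cfg.rate_stim_peak if d == 0 else 0.0
    return cfg.rate_stim_peak * math.exp(-d * d / (2.0 * s * s))


# ---------------------------------------------------------------------------
# Allocation
# ---------------------------------------------------------------------------

def _largest_remainder(total: int, fractions: list[float]) -> list[int]:
    raw = [total * f for f in fractions]
    base = [int(math.floor(r)) for r in raw]
    short = total - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i],
                   reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def _place_on_tree(m: Morphology, tree: str, n: int,
                   rng: np.random.Generator) -> list[tuple[int, float]]:
    """Uniform-per-unit-length placement: (segment_id, pos)."""
    segs = m.dendritic_segments(tree)
    lengths = np.asarray([s.length for s in segs])
    cum = np.cumsum(lengths)
    total = cum[-1]
    out = []
    for u in rng.uniform(0.0, total, size=n):
        k = int(np.searchsorted(cum, u, side="right"))
        k = min(k, len(segs) - 1)
        start = cum[k] - lengths[k]
        out.append((segs[k].segment_id, (u - start) / lengths[k]))
    return out


def allocate_synapses(m: Morphology, model: DistributionModel | str,
                      n_total: int, bg_fraction: float = 0.75,
                      inhibitory_bg_fraction: float = 0.2,
                      seed=0) -> list[SynapseSpec]:
    """Allocate the full synapse population across the trees.

    n_total synapses split into stimulus-driven (1 - bg_fraction) and
    background; a fixed share of the background population is inhibitory
    (GABA_A), the rest excitatory. Counts per (tree, category) follow the
    distribution model by largest-remainder rounding; within a tree,
    locations are uniform per unit dendritic length. Apical
    stimulus-driven synapses get the 10 ms feedback delay.
    """
    if isinstance(model, str):
        model = DISTRIBUTION_MODELS[model]
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    for tree in ("apical", "basal"):
        if not m.has_tree(tree):
            raise ValueError(f"morphology has no {tree} tree")
    rng = np.random.default_rng(seed)
    n_bg = int(round(n_total * bg_fraction))
    n_stim = n_total - n_bg
    n_inh = int(round(n_bg * inhibitory_bg_fraction))
    n_bg_exc = n_bg - n_inh

    stim_b, stim_a = _largest_remainder(
        n_stim, [model.basal_fraction_stim, model.apical_fraction_stim])
    bg_b, bg_a = _largest_remainder(
        n_bg_exc, [model.basal_fraction_bg, model.apical_fraction_bg])
    inh_b, inh_a, inh_s = _largest_remainder(
        n_inh, [model.basal_fraction_inhib, model.apical_fraction_inhib,
                model.soma_fraction_inhib])

    specs: list[SynapseSpec] = []
    sid = 0

    def add(tree: str, n: int, kind: str, role: str) -> None:
        nonlocal sid
        if tree == "soma":
            places = [(m.root.segment_id, 0.5)] * n
        else:
            places = _place_on_tree(m, tree, n, rng)
        delay = APICAL_STIM_DELAY_MS if (tree == "apical"
                                         and role == "stimulus") else 0.0
        for seg_id, pos in places:
            specs.append(SynapseSpec(sid, seg_id, kind, role, pos,
                                     transmission_delay=delay))
            sid += 1

    add("basal", stim_b, "exc", "stimulus")
    add("apical", stim_a, "exc", "stimulus")
    add("basal", bg_b, "exc", "background")
    add("apical", bg_a, "exc", "background")
    add("basal", inh_b, "inh", "background")
    add("apical", inh_a, "inh", "background")
    add("soma", inh_s, "inh", "background")
    return specs


def assign_preferences(specs: list[SynapseSpec], m: Morphology,
                       apical_mean: float, basal_mean: float,
                       sigma: float, seed) -> list[SynapseSpec]:
    """Draw per-synapse orientation preferences for stimulus-driven
    synapses: apical from N(apical_mean, sigma), basal from
    N(basal_mean, sigma), wrapped to [0, 180)."""
    tree_of = {sid: seg.tree_label for sid, seg in m.segments.items()}
    stim = [s for s in specs if s.role == "stimulus"]
    ap = [s for s in stim if tree_of[s.segment_id] == "apical"]
    ba = [s for s in stim if tree_of[s.segment_id] == "basal"]
    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    ss = root.spawn(2)
    prefs_a = sample_preferences(len(ap), apical_mean, sigma, ss[0])
    prefs_b = sample_preferences(len(ba), basal_mean, sigma, ss[1])
    pref_of = {}
    for s, p in zip(ap, prefs_a):
        pref_of[s.synapse_id] = p
    for s, p in zip(ba, prefs_b):
        pref_of[s.synapse_id] = p
    return [s.with_pref(pref_of[s.synapse_id])
            if s.synapse_id in pref_of else s for s in specs]


# ---------------------------------------------------------------------------
# Poisson trains
# ---------------------------------------------------------------------------

def generate_spike_trains(specs: list[SynapseSpec], cfg: StimulusConfig,
                          duration: float, seed) -> list[EventTrain]:
    """Homogeneous Poisson trains, one independent substream per synapse.

    Background synapses fire at cfg.rate_background over [0, duration];
    stimulus-driven synapses fire at their tuned rate over
    [onset, duration] (silent for spontaneous runs). Transmission delays
    are applied at delivery time by the engine, not baked into the train.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    trains = []
    for s in specs:
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=root.entropy,
                spawn_key=tuple(root.spawn_key) + (s.synapse_id,)))
        if s.role == "background":
            rate, t0, t1 = cfg.rate_background, 0.0, duration
        else:
            rate = tuned_rate(s.theta_pref, cfg.theta_stim, cfg) \
                if s.theta_pref is not None else 0.0
            t0, t1 = cfg.onset, duration
        window = max(t1 - t0, 0.0)
        lam = rate * window / 1000.0
        n = rng.poisson(lam) if lam > 0 else 0
        times = np.sort(rng.uniform(t0, t1, size=n)) if n else np.empty(0)
        trains.append(EventTrain(s.synapse_id, times))
    return trains


# ---------------------------------------------------------------------------
# Serialization (replay tables)
# ---------------------------------------------------------------------------

def synapses_to_frame(specs: list[SynapseSpec]) -> pd.DataFrame:
    return pd.DataFrame([{
        "synapse_id": s.synapse_id, "segment_id": s.segment_id,
        "kind": s.kind, "role": s.role, "pos": s.pos,
        "theta_pref": s.theta_pref if s.theta_pref is not None else np.nan,
        "weight_scale": s.weight_scale, "delay": s.transmission_delay,
    } for s in specs])


def trains_to_frame(trains: list[EventTrain]) -> pd.DataFrame:
    rows = [(tr.synapse_id, t) for tr in trains for t in tr.event_times]
    return pd.DataFrame(rows, columns=["synapse_id", "t_ms"])


def frame_to_trains(df: pd.DataFrame,
                    specs: list[SynapseSpec]) -> list[EventTrain]:
    by_id = {int(k): np.sort(np.asarray(v))
             for k, v in df.groupby("synapse_id")["t_ms"]}
    return [EventTrain(s.synapse_id,
                       by_id.get(s.synapse_id, np.empty(0)))
            for s in specs]
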