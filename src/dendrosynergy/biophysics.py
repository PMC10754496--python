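"""Membrane mechanisms: conductance-density rules and channel kinetics.

Density rules
-------------
The model carries seven voltage/calcium-gated conductances (Na, Kdr, Km,
KA, CaT, CaHVA, KCa) whose densities depend on compartment region
(soma/apical/basal), path distance x (um) and diameter d (um). The rules
are evaluated exactly as published for the source cell (sin arguments in
radians; densities reported in the published mS/cm^2 figures). The apical
CaT/CaHVA sinusoid crosses zero at x ~ 251.3 um and would go negative just
before its 260 um cutover; negative values are clamped to zero, which the
density-rule contract (density >= 0) requires. The resulting discontinuity
at x = 260 um (0 -> 0.012 for CaT) is real and is left in place.

Kinetics
--------
The published description names the channel families but not their rate
functions; the kinetics here are a documented standard set —
Hodgkin-Huxley-style Na/Kdr/Km/CaHVA/KCa after Mainen & Sejnowski (1996),
a Destexhe-type low-threshold CaT current, and a Migliore-style A-type
current — with no temperature corrections. Gating advances by the exact
exponential update x <- xinf + (x - xinf) exp(-dt/tau), which is
unconditionally stable and keeps gates in [0, 1] for any dt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .morphology import PassiveParams, Segment

CHANNELS = ("Na", "Kdr", "Km", "KA", "CaT", "CaHVA", "KCa")

# Reversal potentials, mV. Not printed in the source description;
# standard values, overridable via ReversalPotentials.
@dataclass(frozen=True)
class ReversalPotentials:
    e_na: float = 60.0
    e_k: float = -80.0
    e_ca: float = 140.0


@dataclass(frozen=True)
class CalciumDynamics:
    """First-order intracellular Ca pool: influx from Ca currents, exponential
    pump/decay back to the resting level.

    depth: submembrane shell depth, um; tau: decay, ms; ca_rest: mM.
    """
    depth: float = 0.1
    tau: float = 200.0
    ca_rest: float = 1e-4

    @property
    def influx_factor(self) -> float:
        """mM/ms per uA/cm^2 of inward Ca current (2F, shell depth)."""
        return 1e4 * 1e-3 / (2.0 * 96485.0 * self.depth)


# ---------------------------------------------------------------------------
# Density rules (mS/cm^2 as published; x in um, d in um)
# ---------------------------------------------------------------------------

def _apical_sine(amplitude: float, x: float, plateau: float) -> float:
    if x <= 260.0:
        return max(0.0, amplitude * math.sin(0.009 * x + 0.88))
    return plateau


def _density(channel: str, region: str, x: float, d: float) -> float:
    if channel == "Na":
        return 0.505 if region == "soma" else 0.303
    if channel == "Kdr":
        return 0.05 if region == "soma" else 1.5e-3
    if channel == "Km":
        return 2.8e-3 if region == "soma" else 1.27e-3
    if channel == "KA":
        if region == "soma":
            return 5.4
        return 108.0 if d <= 0.8 else 10.8
    if channel == "CaT":
        if region == "soma":
            return 0.03
        if region == "apical":
            return _apical_sine(0.029, x, 0.012)
        return 0.03 + 6e-5 * x
    if channel == "CaHVA":
        if region == "soma":
            return 0.05e-3
        if region == "apical":
            return _apical_sine(0.049e-3, x, 0.02e-3)
        return 0.05e-3 + 1e-7 * x
    if channel == "KCa":
        return 2.1e-3
    raise KeyError(f"unknown channel {channel!r}")


@dataclass(frozen=True)
class ChannelDensityRule:
    """Density of one channel in one region as a function of (x, d)."""
    channel: str
    region: str

    def __call__(self, x: float, d: float) -> float:
        return _density(self.channel, self.region, x, d)


# The published density table mixes unit conventions across rows (its Na row
# can only support the validated action potentials when read in S/cm^2, while
# its KA row — 108 mS/cm^2 on thin dendrites, the classic A-current figure —
# is already in mS/cm^2). `UNIT_SCALE` reconciles each row into the simulator's
# mS/cm^2; it is part of the package's documented non-reproduction parameter
# set and is config-exposed.
UNIT_SCALE = {
    "Na": 1000.0, "Kdr": 1000.0, "Km": 1000.0,
    "KA": 1.0, "CaT": 1.0, "CaHVA": 1000.0, "KCa": 1000.0,
}


@dataclass
class DensityRuleSet:
    """The full region/distance/diameter-dependent conductance map.

    `unit_scale` maps each channel's published figure onto the simulator's
    mS/cm^2 scale (see UNIT_SCALE). `scales` applies per-(channel, region)
    multipliers, used by the sodium-block and sensitivity protocols.
    """
    unit_scale: dict[str, float] = field(
        default_factory=lambda: dict(UNIT_SCALE))
    scales: dict[tuple[str, str], float] = field(default_factory=dict)

    def conductance_at(self, channel: str, segment: Segment) -> float:
        """Published-units density (mS/cm^2) for a segment, before scaling."""
        if channel not in CHANNELS:
            raise KeyError(f"unknown channel {channel!r}")
        return _density(channel, segment.tree_label,
                        segment.path_distance, segment.diameter)

    def density_si(self, channel: str, region: str, x: float, d: float) -> float:
        """Density in mS/cm^2 on the simulator scale, after unit
        reconciliation and any protocol scaling."""
        base = _density(channel, region, x, d) * self.unit_scale[channel]
        return base * self.scales.get((channel, region), 1.0)

    def scaled(self, channel: str, region: str, factor: float) -> "DensityRuleSet":
        scales = dict(self.scales)
        scales[(channel, region)] = scales.get((channel, region), 1.0) * factor
        return DensityRuleSet(dict(self.unit_scale), scales)

    def passive_copy(self) -> "DensityRuleSet":
        scales = {(c, r): 0.0 for c in CHANNELS
                  for r in ("soma", "apical", "basal")}
        return DensityRuleSet(dict(self.unit_scale), scales)


def conductance_at(rule_set: DensityRuleSet, channel: str,
                   segment: Segment) -> float:
    """Published-units (mS/cm^2) density for `channel` on `segment`."""
    return rule_set.conductance_at(channel, segment)


# ---------------------------------------------------------------------------
# Gating kinetics (pure-python reference; the engine kernel mirrors these)
# ---------------------------------------------------------------------------

def _trap(v: float, th: float, a: float, q: float) -> float:
    """a*(v-th)/(1-exp(-(v-th)/q)) with the removable singularity handled."""
    x = (v - th) / q
    if abs(x) < 1e-6:
        return a * q * (1.0 + x / 2.0)
    return a * (v - th) / (1.0 - math.exp(-x))


def na_m_rates(v: float) -> tuple[float, float]:
    a = _trap(v, -25.0, 0.182, 9.0)
    b = _trap(-v, 25.0, 0.124, 9.0)
    return a / (a + b), 1.0 / (a + b)


def na_h_rates(v: float) -> tuple[float, float]:
    a = _trap(v, -50.0, 0.024, 5.0)
    b = _trap(-v, 75.0, 0.0091, 5.0)
    hinf = 1.0 / (1.0 + math.exp((v + 65.0) / 6.2))
    return hinf, 1.0 / (a + b)


def kdr_n_rates(v: float) -> tuple[float, float]:
    a = _trap(v, 25.0, 0.02, 9.0)
    b = _trap(-v, -25.0, 0.002, 9.0)
    return a / (a + b), 1.0 / (a + b)


def km_n_rates(v: float) -> tuple[float, float]:
    a = _trap(v, -30.0, 0.001, 9.0)
    b = _trap(-v, 30.0, 0.001, 9.0)
    return a / (a + b), 1.0 / (a + b)


def ka_n_rates(v: float) -> tuple[float, float]:
    ninf = 1.0 / (1.0 + math.exp(-(v + 31.0) / 6.0))
    return ninf, 1.0


def ka_l_rates(v: float) -> tuple[float, float]:
    linf = 1.0 / (1.0 + math.exp((v + 71.0) / 6.0))
    tau = max(5.0, 0.26 * (v + 50.0))
    return linf, tau


def cat_m_rates(v: float) -> tuple[float, float]:
    minf = 1.0 / (1.0 + math.exp(-(v + 57.0) / 6.2))
    tau = 0.612 + 1.0 / (math.exp(-(v + 132.0) / 16.7)
                         + math.exp((v + 16.8) / 18.2))
    return minf, tau


def cat_h_rates(v: float) -> tuple[float, float]:
    hinf = 1.0 / (1.0 + math.exp((v + 81.0) / 4.0))
    if v < -80.0:
        tau = math.exp((v + 467.0) / 66.6)
    else:
        tau = 28.0 + math.exp(-(v + 22.0) / 10.5)
    return hinf, tau


def hva_m_rates(v: float) -> tuple[float, float]:
    a = 0.055 * _trap(v, -27.0, 1.0, 3.8)
    b = 0.94 * math.exp((-75.0 - v) / 17.0)
    return a / (a + b), 1.0 / (a + b)


def hva_h_rates(v: float) -> tuple[float, float]:
    a = 0.000457 * math.exp((-13.0 - v) / 50.0)
    b = 0.0065 / (math.exp((-v - 15.0) / 28.0) + 1.0)
    return a / (a + b), 1.0 / (a + b)


def kca_n_rates(ca: float) -> tuple[float, float]:
    a = 1.0 * ca  # ca in mM
    b = 0.02
    return a / (a + b), 1.0 / (a + b)


GATE_RATE_FNS = {
    "na_m": na_m_rates, "na_h": na_h_rates, "kdr_n": kdr_n_rates,
    "km_n": km_n_rates, "ka_n": ka_n_rates, "ka_l": ka_l_rates,
    "cat_m": cat_m_rates, "cat_h": cat_h_rates, "hva_m": hva_m_rates,
    "hva_h": hva_h_rates,
}


def exact_gate_update(x: float, xinf: float, tau: float, dt: float) -> float:
    """x <- xinf + (x - xinf) exp(-dt/tau): exact for frozen V over dt."""
    return xinf + (x - xinf) * math.exp(-dt / tau)


@dataclass
class ChannelState:
    """Per-segment gating variables and calcium for the reference stepper."""
    v_init: float = -79.0
    gates: dict[str, float] = field(default_factory=dict)
    ca: float = 1e-4

    def __post_init__(self) -> None:
        if not self.gates:
            for name, fn in GATE_RATE_FNS.items():
                self.gates[name] = fn(self.v_init)[0]
            self.gates["kca_n"] = kca_n_rates(self.ca)[0]


def step_channel_states(state: ChannelState, v: float, dt: float,
                        ca_influx: float = 0.0,
                        ca_dyn: CalciumDynamics = CalciumDynamics()) -> ChannelState:
    """Advance all gates one step at voltage v; returns a new state.

    `ca_influx` is the inward calcium current density in uA/cm^2 (>= 0 for
    inward, as a magnitude). Raises on non-finite voltage.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not math.isfinite(v):
        raise FloatingPointError(f"non-finite voltage {v}")
    gates = {}
    for name, fn in GATE_RATE_FNS.items():
        xinf, tau = fn(v)
        gates[name] = exact_gate_update(state.gates[name], xinf, tau, dt)
    # calcium: exponential relaxation toward (rest + influx*tau)
    ca_ss = ca_dyn.ca_rest + ca_dyn.influx_factor * ca_influx * ca_dyn.tau
    ca = ca_ss + (state.ca - ca_ss) * math.exp(-dt / ca_dyn.tau)
    ca = max(ca, 1e-9)
    xinf, tau = kca_n_rates(ca)
    gates["kca_n"] = exact_gate_update(state.gates["kca_n"], xinf, tau, dt)
    new = ChannelState(v_init=v, gates=gates, ca=ca)
    return new


def open_fractions(gates: dict[str, float]) -> dict[str, float]:
    """Channel open probability from gate products."""
    return {
        "Na": gates["na_m"] ** 3 * gates["na_h"],
        "Kdr": gates["kdr_n"],
        "Km": gates["km_n"],
        "KA": gates["ka_n"] * gates["ka_l"],
        "CaT": gates["cat_m"] ** 2 * gates["cat_h"],
        "CaHVA": gates["hva_m"] ** 2 * gates["hva_h"],
        "KCa": gates["kca_n"],
    }


def membrane_current(state: ChannelState, v: float,
                     densities: dict[str, float],
                     passive: PassiveParams,
                     rev: ReversalPotentials = ReversalPotentials()) -> float:
    """Total ionic current density, uA/cm^2 (positive = outward).

    `densities` in mS/cm^2 (simulator scale). Leak always included.
    """
    e_of = {"Na": rev.e_na, "Kdr": rev.e_k, "Km": rev.e_k, "KA": rev.e_k,
            "CaT": rev.e_ca, "CaHVA": rev.e_ca, "KCa": rev.e_k}
    opens = open_fractions(state.gates)
    i = passive.g_leak * 1e3 * (v - passive.e_leak)  # S->mS per cm^2
    for ch, g in densities.items():
        i += g * opens[ch] * (v - e_of[ch])
    return i
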