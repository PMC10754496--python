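"""Branched-cable simulation engine.

The morphology is discretized into isopotential compartments (at most a
configurable fraction of the local space constant long). Voltage advances
by a first-order implicit (backward Euler) step: ionic and synaptic
conductances are frozen at their start-of-step gating values, which makes
the membrane term linear in V, and the resulting symmetric tree system is
solved exactly each step by Hines elimination (leaf-to-root forward sweep,
root-to-leaf back-substitution). Gating variables advance by the exact
exponential update between voltage steps. The whole stepping loop is
compiled with numba.

Units: mV, ms, nA, uS, nF; conductance densities mS/cm^2; areas cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .morphology import Morphology, PassiveParams, space_constant
from .biophysics import (CHANNELS, CalciumDynamics, DensityRuleSet,
                         ReversalPotentials)
from .synapses import KINETICS, SynapseSpec, EventTrain, mg_block_params

TREE_CODE = {"soma": 0, "apical": 1, "basal": 2}


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Run-level parameters: dt, duration, onset and recording sites."""
    dt: float = 0.1
    duration: float = 2500.0
    stimulus_onset: float = 500.0
    record: str = "soma"  # "soma" | "all" | explicit in run()
    v_init: float | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.stimulus_onset:
            raise ValueError("duration must cover the stimulus onset")


@dataclass(frozen=True)
class InterventionSpec:
    """Windowed multiplicative scaling of one parameter on one tree.

    target_parameter: 'g_Na' (sodium conductance density) or
    'stim_syn_weight' (stimulus-driven AMPA/NMDA weights). The window is
    closed at both endpoints.
    """
    target_tree: str
    target_parameter: str
    scale: float
    window_start: float
    window_end: float

    def __post_init__(self) -> None:
        if self.target_tree not in ("apical", "basal"):
            raise ValueError("target_tree must be apical or basal")
        if self.target_parameter not in ("g_Na", "stim_syn_weight"):
            raise ValueError("unknown target_parameter")
        if not self.window_start < self.window_end:
            raise ValueError("window_start must precede window_end")
        if self.scale < 0:
            raise ValueError("scale must be non-negative")


@dataclass(frozen=True)
class CurrentClamp:
    """Step current injection at a segment (nA), for validation protocols."""
    segment_id: int
    amplitude: float
    start: float
    stop: float


@dataclass
class SimulationResult:
    traces: np.ndarray            # (n_record, n_steps + 1) mV
    record_segments: list[int]    # segment id per trace row
    times: np.ndarray             # ms
    somatic_spike_times: np.ndarray
    config_echo: dict

    def trace_for(self, segment_id: int) -> np.ndarray:
        return self.traces[self.record_segments.index(segment_id)]


# ---------------------------------------------------------------------------
# System assembly
# ---------------------------------------------------------------------------

class System:
    """Compartmentalized cell: topology, passive load, densities, synapses."""

    def __init__(self, morphology: Morphology, passive: PassiveParams,
                 rules: DensityRuleSet,
                 synapses: list[SynapseSpec] | None = None,
                 lambda_fraction: float = 0.1,
                 max_compartments: int = 20000,
                 rev: ReversalPotentials = ReversalPotentials(),
                 ca_dyn: CalciumDynamics = CalciumDynamics()):
        self.morphology = morphology
        self.passive = passive
        self.rules = rules
        self.rev = rev
        self.ca_dyn = ca_dyn
        self.synapses = list(synapses or [])
        self.lambda_fraction = lambda_fraction
        self._build(max_compartments)
        self._bind_synapses()

    # -- compartments ------------------------------------------------------
    def _build(self, max_compartments: int) -> None:
        m, passive = self.morphology, self.passive
        comp_seg: list[int] = []
        comp_tree: list[int] = []
        area: list[float] = []
        half_r: list[float] = []      # axial half-resistance, Ohm
        parent: list[int] = []
        seg_first: dict[int, int] = {}
        seg_last: dict[int, int] = {}

        soma = m.root
        comp_seg.append(soma.segment_id)
        comp_tree.append(0)
        area.append(math.pi * soma.diameter**2 * 1e-8)  # sphere, cm^2
        half_r.append(0.0)
        parent.append(-1)
        seg_first[soma.segment_id] = seg_last[soma.segment_id] = 0

        def visit(seg_id: int) -> None:
            seg = m.segments[seg_id]
            if seg.tree_label != "soma":
                lam = space_constant(seg.diameter, passive)
                n_c = max(1, math.ceil(seg.length / (self.lambda_fraction * lam)))
                ell = seg.length / n_c
                d_cm = seg.diameter * 1e-4
                ell_cm = ell * 1e-4
                a = math.pi * d_cm * ell_cm
                hr = passive.r_a * (ell_cm / 2.0) / (math.pi * (d_cm / 2.0) ** 2)
                p = seg_last[seg.parent_id]
                for k in range(n_c):
                    idx = len(comp_seg)
                    comp_seg.append(seg_id)
                    comp_tree.append(TREE_CODE[seg.tree_label])
                    area.append(a)
                    half_r.append(hr)
                    parent.append(p)
                    p = idx
                seg_first[seg_id] = len(comp_seg) - n_c
                seg_last[seg_id] = len(comp_seg) - 1
            for c in m.children.get(seg_id, []):
                visit(c)

        for c in m.children.get(soma.segment_id, []):
            visit(c)
        n = len(comp_seg)
        if n > max_compartments:
            raise SimulationError(
                f"discretization produced {n} compartments "
                f"(> {max_compartments}); increase lambda_fraction or "
                f"max_compartments")
        self.n_comp = n
        self.comp_seg = np.asarray(comp_seg, dtype=np.int64)
        self.comp_tree = np.asarray(comp_tree, dtype=np.int64)
        self.area = np.asarray(area)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.seg_first, self.seg_last = seg_first, seg_last
        # axial conductance to parent, uS
        gax = np.zeros(n)
        for i in range(1, n):
            r = half_r[i] + half_r[self.parent[i]]
            gax[i] = 1e6 / r
        self.gax = gax
        # capacitance, nF
        self.cap = passive.c_m * self.area * 1e3
        # leak, uS
        self.g_leak = passive.g_leak * self.area * 1e6
        # channel densities, mS/cm^2 on simulator scale, per compartment
        gbar = np.zeros((len(CHANNELS), n))
        for i in range(n):
            seg = m.segments[int(self.comp_seg[i])]
            region = seg.tree_label
            for ci, ch in enumerate(CHANNELS):
                gbar[ci, i] = self.rules.density_si(
                    ch, region, seg.path_distance, seg.diameter)
        self.gbar_density = gbar
        self.gbar_abs = gbar * self.area[None, :] * 1e3  # uS

    def seg_mid_comp(self, segment_id: int) -> int:
        """Compartment nearest the segment midpoint (recording site)."""
        first, last = self.seg_first[segment_id], self.seg_last[segment_id]
        return (first + last) // 2

    def tree_mask(self, tree: str) -> np.ndarray:
        return self.comp_tree == TREE_CODE[tree]

    # -- synapse binding ---------------------------------------------------
    def _bind_synapses(self) -> None:
        """Expand synapse specs into channel instances bound to compartments.

        Excitatory synapses are co-located AMPA+NMDA pairs sharing one
        event train; inhibitory synapses are single GABA_A instances.
        """
        inst_comp, inst_kind, inst_g, inst_syn = [], [], [], []
        inst_stim, inst_tree = [], []
        for s in self.synapses:
            if s.segment_id == self.morphology.root.segment_id:
                comp = 0
            else:
                first = self.seg_first[s.segment_id]
                last = self.seg_last[s.segment_id]
                comp = first + int(round(s.pos * (last - first)))
            kinds = ("AMPA", "NMDA") if s.kind == "exc" else ("GABA_A",)
            for kname in kinds:
                kin = KINETICS[kname]
                inst_comp.append(comp)
                inst_kind.append({"AMPA": 0, "NMDA": 1, "GABA_A": 2}[kname])
                inst_g.append(kin.g_max * 1e-3 * kin.norm_factor
                              * s.weight_scale)  # uS at peak per unit event
                inst_syn.append(s.synapse_id)
                inst_stim.append(1 if s.role == "stimulus" else 0)
                inst_tree.append(TREE_CODE[
                    self.morphology.segments[s.segment_id].tree_label])
        self.inst_comp = np.asarray(inst_comp, dtype=np.int64)
        self.inst_kind = np.asarray(inst_kind, dtype=np.int64)
        self.inst_gmax = np.asarray(inst_g, dtype=float)
        self.inst_syn = np.asarray(inst_syn, dtype=np.int64)
        self.inst_stim = np.asarray(inst_stim, dtype=np.int64)
        self.inst_tree = np.asarray(inst_tree, dtype=np.int64)

    # -- modified copies ---------------------------------------------------
    def with_rules(self, rules: DensityRuleSet) -> "System":
        return System(self.morphology, self.passive, rules, self.synapses,
                      self.lambda_fraction, rev=self.rev, ca_dyn=self.ca_dyn)

    def sodium_block(self, tree: str, scale: float = 0.0) -> "System":
        """Whole-run scaling of g_Na on one tree (0 = full block)."""
        return self.with_rules(self.rules.scaled("Na", tree, scale))

    def active_only_segment(self, segment_id: int | None) -> "System":
        """Copy in which every compartment outside `segment_id` is passive
        (all seven active densities zeroed); None means fully passive."""
        sys2 = System(self.morphology, self.passive, self.rules,
                      self.synapses, self.lambda_fraction,
                      rev=self.rev, ca_dyn=self.ca_dyn)
        mask = (sys2.comp_seg != (-1 if segment_id is None else segment_id))
        sys2.gbar_density[:, mask] = 0.0
        sys2.gbar_abs[:, mask] = 0.0
        return sys2

    def passive_copy(self) -> "System":
        return self.active_only_segment(None)

    def ablated(self, tree: str = "apical") -> "System":
        """Remove an entire tree (compartments and its synapses)."""
        keep = {sid for sid, seg in self.morphology.segments.items()
                if seg.tree_label != tree}
        segs = {sid: self.morphology.segments[sid] for sid in keep}
        m2 = Morphology(segs)
        syn2 = [s for s in self.synapses if s.segment_id in keep]
        return System(m2, self.passive, self.rules, syn2,
                      self.lambda_fraction, rev=self.rev, ca_dyn=self.ca_dyn)

    def with_weight_scale(self, factor: float,
                          roles: tuple[str, ...] = ("stimulus", "background"),
                          kinds: tuple[str, ...] = ("exc",)) -> "System":
        syn2 = [s.with_weight(s.weight_scale * factor)
                if (s.role in roles and s.kind in kinds) else s
                for s in self.synapses]
        return System(self.morphology, self.passive, self.rules, syn2,
                      self.lambda_fraction, rev=self.rev, ca_dyn=self.ca_dyn)

    def with_synapses(self, synapses: list[SynapseSpec]) -> "System":
        return System(self.morphology, self.passive, self.rules, synapses,
                      self.lambda_fraction, rev=self.rev, ca_dyn=self.ca_dyn)


# ---------------------------------------------------------------------------
# The compiled stepping kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rates(v, ca, xinf, tau):
    """Fill xinf/tau (11,) for one compartment at voltage v, calcium ca."""
    # Na m
    x = (v + 25.0) / 9.0
    a = 0.182 * 9.0 * (1.0 + x / 2.0) if abs(x) < 1e-6 \
        else 0.182 * (v + 25.0) / (1.0 - math.exp(-x))
    xb = (-v - 25.0) / 9.0
    b = 0.124 * 9.0 * (1.0 + xb / 2.0) if abs(xb) < 1e-6 \
        else 0.124 * (-v - 25.0) / (1.0 - math.exp(-xb))
    xinf[0] = a / (a + b); tau[0] = 1.0 / (a + b)
    # Na h
    x = (v + 50.0) / 5.0
    a = 0.024 * 5.0 * (1.0 + x / 2.0) if abs(x) < 1e-6 \
        else 0.024 * (v + 50.0) / (1.0 - math.exp(-x))
    xb = (-v - 75.0) / 5.0
    b = 0.0091 * 5.0 * (1.0 + xb / 2.0) if abs(xb) < 1e-6 \
        else 0.0091 * (-v - 75.0) / (1.0 - math.exp(-xb))
    xinf[1] = 1.0 / (1.0 + math.exp((v + 65.0) / 6.2))
    tau[1] = 1.0 / (a + b)
    # Kdr n
    x = (v - 25.0) / 9.0
    a = 0.02 * 9.0 * (1.0 + x / 2.0) if abs(x) < 1e-6 \
        else 0.02 * (v - 25.0) / (1.0 - math.exp(-x))
    xb = (-v + 25.0) / 9.0
    b = 0.002 * 9.0 * (1.0 + xb / 2.0) if abs(xb) < 1e-6 \
        else 0.002 * (-v + 25.0) / (1.0 - math.exp(-xb))
    xinf[2] = a / (a + b); tau[2] = 1.0 / (a + b)
    # Km n
    x = (v + 30.0) / 9.0
    a = 0.001 * 9.0 * (1.0 + x / 2.0) if abs(x) < 1e-6 \
        else 0.001 * (v + 30.0) / (1.0 - math.exp(-x))
    xb = (-v - 30.0) / 9.0
    b = 0.001 * 9.0 * (1.0 + xb / 2.0) if abs(xb) < 1e-6 \
        else 0.001 * (-v - 30.0) / (1.0 - math.exp(-xb))
    xinf[3] = a / (a + b); tau[3] = 1.0 / (a + b)
    # KA n, l
    xinf[4] = 1.0 / (1.0 + math.exp(-(v + 31.0) / 6.0)); tau[4] = 1.0
    xinf[5] = 1.0 / (1.0 + math.exp((v + 71.0) / 6.0))
    tl = 0.26 * (v + 50.0)
    tau[5] = tl if tl > 5.0 else 5.0
    # CaT m, h
    xinf[6] = 1.0 / (1.0 + math.exp(-(v + 57.0) / 6.2))
    tau[6] = 0.612 + 1.0 / (math.exp(-(v + 132.0) / 16.7)
                            + math.exp((v + 16.8) / 18.2))
    xinf[7] = 1.0 / (1.0 + math.exp((v + 81.0) / 4.0))
    tau[7] = math.exp((v + 467.0) / 66.6) if v < -80.0 \
        else 28.0 + math.exp(-(v + 22.0) / 10.5)
    # CaHVA m, h
    u = v + 27.0
    a = 0.055 * 3.8 * (1.0 + u / 7.6) if abs(u / 3.8) < 1e-6 \
        else 0.055 * u / (1.0 - math.exp(-u / 3.8))
    b = 0.94 * math.exp((-75.0 - v) / 17.0)
    xinf[8] = a / (a + b); tau[8] = 1.0 / (a + b)
    a = 0.000457 * math.exp((-13.0 - v) / 50.0)
    b = 0.0065 / (math.exp((-v - 15.0) / 28.0) + 1.0)
    xinf[9] = a / (a + b); tau[9] = 1.0 / (a + b)
    # KCa n (calcium-dependent)
    a = 1.0 * ca
    b = 0.02
    xinf[10] = a / (a + b); tau[10] = 1.0 / (a + b)


@njit(cache=True)
def _integrate(n, parent, gax, cap, g_leak, e_leak, gbar_abs, gbar_density,
               comp_tree, dt, n_steps,
               e_na, e_k, e_ca, ca_rest, ca_tau, ca_phi,
               inst_comp, inst_kind, inst_gmax, inst_stim, inst_tree,
               d1, d2, e_syn, mg_eta, mg_gamma,
               ev_step, ev_inst,
               iv_tree, iv_param, iv_scale, iv_s0, iv_s1,
               inj_comp, inj_amp, inj_s0, inj_s1,
               rec_idx, v0):
    n_rec = rec_idx.shape[0]
    out = np.empty((n_rec, n_steps + 1))
    v = np.full(n, v0)
    ca = np.full(n, ca_rest)
    gates = np.empty((11, n))
    xinf = np.empty(11)
    tau = np.empty(11)
    for i in range(n):
        _rates(v[i], ca[i], xinf, tau)
        for g in range(11):
            gates[g, i] = xinf[g]
    n_inst = inst_comp.shape[0]
    A = np.zeros(n_inst)
    B = np.zeros(n_inst)
    diag = np.empty(n)
    rhs = np.empty(n)
    ep = 0
    n_ev = ev_step.shape[0]
    for r in range(n_rec):
        out[r, 0] = v[rec_idx[r]]
    exp_ca = math.exp(-dt / ca_tau)

    for step in range(n_steps):
        # intervention scales for this step (closed windows)
        na_scale_ap = 1.0; na_scale_ba = 1.0
        w_scale_ap = 1.0; w_scale_ba = 1.0
        for k in range(iv_tree.shape[0]):
            if iv_s0[k] <= step <= iv_s1[k]:
                if iv_param[k] == 0:
                    if iv_tree[k] == 1:
                        na_scale_ap *= iv_scale[k]
                    else:
                        na_scale_ba *= iv_scale[k]
                else:
                    if iv_tree[k] == 1:
                        w_scale_ap *= iv_scale[k]
                    else:
                        w_scale_ba *= iv_scale[k]

        # synaptic state: decay then deliver events scheduled at this step
        for j in range(n_inst):
            A[j] *= d1[j]
            B[j] *= d2[j]
        while ep < n_ev and ev_step[ep] == step:
            j = ev_inst[ep]
            A[j] += 1.0
            B[j] += 1.0
            ep += 1

        # membrane assembly
        for i in range(n):
            vi = v[i]
            _rates(vi, ca[i], xinf, tau)
            for g in range(11):
                gates[g, i] = xinf[g] + (gates[g, i] - xinf[g]) \
                    * math.exp(-dt / tau[g])
            m3h = gates[0, i] ** 3 * gates[1, i]
            o_kdr = gates[2, i]
            o_km = gates[3, i]
            o_ka = gates[4, i] * gates[5, i]
            o_cat = gates[6, i] ** 2 * gates[7, i]
            o_hva = gates[8, i] ** 2 * gates[9, i]
            o_kca = gates[10, i]
            na_sc = 1.0
            if comp_tree[i] == 1:
                na_sc = na_scale_ap
            elif comp_tree[i] == 2:
                na_sc = na_scale_ba
            g_na = gbar_abs[0, i] * m3h * na_sc
            g_k = (gbar_abs[1, i] * o_kdr + gbar_abs[2, i] * o_km
                   + gbar_abs[3, i] * o_ka + gbar_abs[6, i] * o_kca)
            g_ca = gbar_abs[4, i] * o_cat + gbar_abs[5, i] * o_hva
            g_tot = g_na + g_k + g_ca + g_leak[i]
            ge_tot = (g_na * e_na + g_k * e_k + g_ca * e_ca
                      + g_leak[i] * e_leak)
            diag[i] = cap[i] / dt + g_tot
            rhs[i] = cap[i] / dt * vi + ge_tot
            # calcium pool from the Ca current density at this step
            ica = (gbar_density[4, i] * o_cat
                   + gbar_density[5, i] * o_hva) * (vi - e_ca)  # uA/cm^2
            ca_ss = ca_rest - ca_phi * ica * ca_tau
            can = ca_ss + (ca[i] - ca_ss) * exp_ca
            ca[i] = can if can > 1e-9 else 1e-9

        # synaptic conductances
        for j in range(n_inst):
            g = inst_gmax[j] * (B[j] - A[j])
            if g != 0.0:
                i = inst_comp[j]
                if inst_kind[j] == 1:  # NMDA magnesium block at V(t)
                    g *= 1.0 / (1.0 + mg_eta * math.exp(-mg_gamma * v[i]))
                if inst_stim[j] == 1 and inst_kind[j] != 2:
                    if inst_tree[j] == 1:
                        g *= w_scale_ap
                    elif inst_tree[j] == 2:
                        g *= w_scale_ba
                diag[i] += g
                rhs[i] += g * e_syn[inst_kind[j]]

        # current clamps
        for k in range(inj_comp.shape[0]):
            if inj_s0[k] <= step < inj_s1[k]:
                rhs[inj_comp[k]] += inj_amp[k]

        # axial coupling on the diagonal
        for i in range(1, n):
            diag[i] += gax[i]
            diag[parent[i]] += gax[i]

        # Hines solve (parents precede children in the ordering)
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = gax[i] / diag[i]
            diag[p] -= f * gax[i]
            rhs[p] += f * rhs[i]
        v[0] = rhs[0] / diag[0]
        for i in range(1, n):
            v[i] = (rhs[i] + gax[i] * v[parent[i]]) / diag[i]

        if step % 200 == 0:
            for i in range(n):
                if not math.isfinite(v[i]):
                    return out, -(i + 1), float(step)

        for r in range(n_rec):
            out[r, step + 1] = v[rec_idx[r]]
    return out, 0, 0.0


# ---------------------------------------------------------------------------
# Run API
# ---------------------------------------------------------------------------

def run(system: System, cfg: SimConfig,
        trains: list[EventTrain] | None = None,
        interventions: list[InterventionSpec] | None = None,
        clamps: list[CurrentClamp] | None = None,
        record_segments: list[int] | None = None,
        spike_threshold: float = 0.0,
        spike_refractory: float = 3.0) -> SimulationResult:
    """Integrate the system and return traces + somatic spike times."""
    trains = trains or []
    interventions = interventions or []
    clamps = clamps or []
    dt = cfg.dt
    n_steps = int(round(cfg.duration / dt))
    v0 = cfg.v_init if cfg.v_init is not None else system.passive.e_leak

    # events -> (step, instance), sorted by step
    syn_to_inst: dict[int, list[int]] = {}
    for j, sid in enumerate(system.inst_syn):
        syn_to_inst.setdefault(int(sid), []).append(j)
    delay = {s.synapse_id: s.transmission_delay for s in system.synapses}
    ev_steps: list[int] = []
    ev_insts: list[int] = []
    for tr in trains:
        insts = syn_to_inst.get(tr.synapse_id)
        if not insts:
            continue
        dly = delay.get(tr.synapse_id, 0.0)
        for t in tr.event_times:
            td = t + dly
            if td < 0 or td > cfg.duration:
                continue
            s = int(round(td / dt))
            if s >= n_steps:
                continue
            for j in insts:
                ev_steps.append(s)
                ev_insts.append(j)
    if ev_steps:
        order = np.argsort(np.asarray(ev_steps), kind="stable")
        ev_step = np.asarray(ev_steps, dtype=np.int64)[order]
        ev_inst = np.asarray(ev_insts, dtype=np.int64)[order]
    else:
        ev_step = np.empty(0, dtype=np.int64)
        ev_inst = np.empty(0, dtype=np.int64)

    # interventions -> step windows (closed)
    n_iv = len(interventions)
    iv_tree = np.empty(n_iv, dtype=np.int64)
    iv_param = np.empty(n_iv, dtype=np.int64)
    iv_scale = np.empty(n_iv)
    iv_s0 = np.empty(n_iv, dtype=np.int64)
    iv_s1 = np.empty(n_iv, dtype=np.int64)
    for k, iv in enumerate(interventions):
        if iv.window_end < 0 or iv.window_start > cfg.duration:
            raise SimulationError("intervention window outside the run")
        iv_tree[k] = TREE_CODE[iv.target_tree]
        iv_param[k] = 0 if iv.target_parameter == "g_Na" else 1
        iv_scale[k] = iv.scale
        iv_s0[k] = max(0, int(math.floor(iv.window_start / dt)))
        iv_s1[k] = min(n_steps, int(math.ceil(iv.window_end / dt)))

    n_cl = len(clamps)
    inj_comp = np.empty(n_cl, dtype=np.int64)
    inj_amp = np.empty(n_cl)
    inj_s0 = np.empty(n_cl, dtype=np.int64)
    inj_s1 = np.empty(n_cl, dtype=np.int64)
    for k, cl in enumerate(clamps):
        inj_comp[k] = system.seg_mid_comp(cl.segment_id) \
            if cl.segment_id != system.morphology.root.segment_id else 0
        inj_amp[k] = cl.amplitude
        inj_s0[k] = int(round(cl.start / dt))
        inj_s1[k] = int(round(cl.stop / dt))

    if record_segments is None:
        if cfg.record == "all":
            record_segments = sorted(system.morphology.segments)
        else:
            record_segments = [system.morphology.root.segment_id]
    rec_idx = np.asarray(
        [0 if s == system.morphology.root.segment_id
         else system.seg_mid_comp(s) for s in record_segments],
        dtype=np.int64)

    kin = [KINETICS[k] for k in ("AMPA", "NMDA", "GABA_A")]
    n_inst = system.inst_comp.shape[0]
    d1 = np.empty(n_inst)
    d2 = np.empty(n_inst)
    for j in range(n_inst):
        kk = kin[int(system.inst_kind[j])]
        d1[j] = math.exp(-dt / kk.tau1)
        d2[j] = math.exp(-dt / kk.tau2)
    e_syn = np.asarray([k.reversal for k in kin])
    mg_eta, mg_gamma = mg_block_params()

    traces, status, when = _integrate(
        system.n_comp, system.parent, system.gax, system.cap, system.g_leak,
        system.passive.e_leak, system.gbar_abs, system.gbar_density,
        system.comp_tree, dt, n_steps,
        system.rev.e_na, system.rev.e_k, system.rev.e_ca,
        system.ca_dyn.ca_rest, system.ca_dyn.tau, system.ca_dyn.influx_factor,
        system.inst_comp, system.inst_kind, system.inst_gmax,
        system.inst_stim, system.inst_tree,
        d1, d2, e_syn, mg_eta, mg_gamma,
        ev_step, ev_inst,
        iv_tree, iv_param, iv_scale, iv_s0, iv_s1,
        inj_comp, inj_amp, inj_s0, inj_s1,
        rec_idx, v0)
    if status < 0:
        comp = -status - 1
        raise SimulationError(
            f"non-finite voltage at t={when * dt:.1f} ms in compartment "
            f"{comp} (segment {int(system.comp_seg[comp])})")

    times = np.arange(n_steps + 1) * dt
    soma_row = None
    root_id = system.morphology.root.segment_id
    if root_id in record_segments:
        soma_row = record_segments.index(root_id)
    if soma_row is not None:
        spikes = detect_somatic_spikes(traces[soma_row], dt,
                                       spike_threshold, spike_refractory)
    else:
        spikes = np.empty(0)
    echo = {
        "dt": dt, "duration": cfg.duration,
        "stimulus_onset": cfg.stimulus_onset,
        "n_compartments": system.n_comp,
        "n_synapses": len(system.synapses),
        "interventions": [
            (iv.target_tree, iv.target_parameter, iv.scale,
             iv.window_start, iv.window_end) for iv in interventions],
        "spike_threshold": spike_threshold,
        "spike_refractory": spike_refractory,
        "density_unit_scale": system.rules.unit_scale,
    }
    return SimulationResult(traces, list(record_segments), times, spikes, echo)


def detect_somatic_spikes(trace: np.ndarray, dt: float,
                          threshold: float = 0.0,
                          refractory: float = 3.0) -> np.ndarray:
    """Upward threshold crossings >= refractory apart, with sub-sample
    linear interpolation of the crossing time."""
    v = np.asarray(trace, dtype=float)
    above = v >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:])
    times = []
    last = -np.inf
    for i in idx:
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        t = (i + frac) * dt
        if t - last >= refractory:
            times.append(t)
            last = t
    return np.asarray(times)
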