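"""Synthetic L2/3-like morphologies and reduced experiment presets.

The generator emulates the qualitative architecture of a layer 2/3
pyramidal cell: several basal stems sprouting from the base of the soma,
and one thick apical trunk that climbs away and splits into a binary
tuft. Dimensions default to values placing most basal path distances
below ~180 um while a substantial fraction of the apical tuft lies
beyond, mirroring the proximal-basal / distal-apical split of the real
cell class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .morphology import Morphology, Segment, load_swc, write_swc


@dataclass(frozen=True)
class SyntheticMorphologyParams:
    n_basal_stems: int = 7
    basal_length_range: tuple[float, float] = (60.0, 100.0)
    basal_diameter_range: tuple[float, float] = (1.3, 1.8)
    basal_branch_prob: float = 0.2     # chance a stem bifurcates once
    apical_trunk_length: float = 180.0
    apical_trunk_diameter: float = 1.8
    tuft_branch_depth: int = 4
    tuft_segment_length: float = 60.0
    tuft_diameter: float = 1.0
    taper: float = 0.95                # child/parent diameter ratio in tuft
    soma_diameter: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tuft_branch_depth < 1:
            raise ValueError("tuft_branch_depth must be >= 1")
        for lo, hi in (self.basal_length_range, self.basal_diameter_range):
            if not (0 < lo <= hi):
                raise ValueError("ranges must be positive and ordered")


def generate_synthetic_morphology(
        params: SyntheticMorphologyParams = SyntheticMorphologyParams(),
        swc_path: str | Path | None = None) -> Morphology:
    """Build a deterministic synthetic pyramidal-like morphology.

    Optionally writes it as SWC (valid input to load_swc).
    """
    rng = np.random.default_rng(params.seed)
    segments: dict[int, Segment] = {
        0: Segment(0, -1, "soma", params.soma_diameter,
                   params.soma_diameter, 0.0, 0, None)}
    next_id = [1]

    def line_points(x0, y0, angle, length, radius, n=3):
        pts = [(x0, y0, 0.0, radius)]
        for k in range(1, n + 1):
            f = k / n
            pts.append((x0 + f * length * math.cos(angle),
                        y0 + f * length * math.sin(angle), 0.0, radius))
        return np.asarray(pts)

    def add_segment(parent_id, tree, length, diameter, x0, y0, angle,
                    parent_path, order):
        seg_id = next_id[0]; next_id[0] += 1
        pts = line_points(x0, y0, angle, length, diameter / 2.0)
        segments[seg_id] = Segment(seg_id, parent_id, tree, length, diameter,
                                   parent_path + length / 2.0, order, pts)
        x1 = x0 + length * math.cos(angle)
        y1 = y0 + length * math.sin(angle)
        return seg_id, x1, y1

    # basal stems, fanning downward
    for i in range(params.n_basal_stems):
        length = rng.uniform(*params.basal_length_range)
        diam = rng.uniform(*params.basal_diameter_range)
        angle = -math.pi / 2 + (i - (params.n_basal_stems - 1) / 2) \
            * (math.pi / max(params.n_basal_stems, 2))
        sid, x1, y1 = add_segment(0, "basal", length, diam, 0.0, 0.0,
                                  angle, 0.0, 0)
        if rng.uniform() < params.basal_branch_prob:
            for da in (-0.4, 0.4):
                clen = rng.uniform(*params.basal_length_range) * 0.6
                add_segment(sid, "basal", clen, diam * 0.8, x1, y1,
                            angle + da, length, 1)

    # apical trunk + binary tuft
    trunk_id, tx, ty = add_segment(0, "apical", params.apical_trunk_length,
                                   params.apical_trunk_diameter, 0.0, 0.0,
                                   math.pi / 2, 0.0, 0)

    def grow_tuft(parent_id, x, y, depth, diameter, parent_path, order,
                  angle):
        if depth > params.tuft_branch_depth:
            return
        for da in (-0.45, 0.45):
            length = params.tuft_segment_length \
                * float(rng.uniform(0.85, 1.15))
            sid, x1, y1 = add_segment(parent_id, "apical", length, diameter,
                                      x, y, angle + da, parent_path, order)
            grow_tuft(sid, x1, y1, depth + 1, diameter * params.taper,
                      parent_path + length, order + 1, angle + da)

    grow_tuft(trunk_id, tx, ty, 1, params.tuft_diameter,
              params.apical_trunk_length, 1, math.pi / 2)

    m = Morphology(segments)
    if swc_path is not None:
        write_swc(m, swc_path)
    return m


@dataclass(frozen=True)
class ExperimentPreset:
    """A named, reduced experiment configuration that runs in minutes."""
    name: str
    n_total_synapses: int
    orientations: tuple[float, ...]
    n_trials: int
    disparities: tuple[float, ...]
    duration: float = 2500.0
    onset: float = 500.0
    seed: int = 7

    def describe(self) -> dict:
        return {k: getattr(self, k) for k in (
            "name", "n_total_synapses", "orientations", "n_trials",
            "disparities", "duration", "onset", "seed")}


def reduced_experiment_presets() -> dict[str, ExperimentPreset]:
    """Desk-scale presets: 'smoke', 'disparity-lite', 'intervention-lite'."""
    return {
        "smoke": ExperimentPreset(
            "smoke", n_total_synapses=7200,
            orientations=(0.0, 50.0, 90.0), n_trials=2,
            disparities=(0.0,)),
        "disparity-lite": ExperimentPreset(
            "disparity-lite", n_total_synapses=7200,
            orientations=tuple(float(o) for o in range(0, 180, 30)),
            n_trials=2, disparities=(0.0, 40.0, 90.0)),
        "intervention-lite": ExperimentPreset(
            "intervention-lite", n_total_synapses=7200,
            orientations=(0.0,), n_trials=2, disparities=(0.0,),
            duration=1500.0),
    }
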