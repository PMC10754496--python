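"""Neuronal morphologies: SWC I/O, the segment tree, and morphometrics.

The working unit here is the *dendritic segment*: an unbranched stretch of
neurite between two branch points (or between a branch point and a tip).
That is the unit at which dendritic nonlinearity, spike thresholds and
attenuation are reported; for simulation each segment is discretized into
shorter iso-potential compartments by the engine.

The soma is modeled as a single isopotential compartment: all SWC soma
samples are merged into one root whose diameter is that of an
equivalent-area sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SWC_SOMA = 1
SWC_BASAL = 3
SWC_APICAL = 4

_TYPE_TO_LABEL = {SWC_SOMA: "soma", SWC_BASAL: "basal", SWC_APICAL: "apical"}
_LABEL_TO_TYPE = {v: k for k, v in _TYPE_TO_LABEL.items()}


class SWCError(ValueError):
    """Malformed or structurally invalid SWC input."""


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane parameters.

    c_m : specific capacitance, uF/cm^2
    r_a : axial resistivity, Ohm*cm
    g_leak : leak conductance density, S/cm^2 (1/17300 gives tau = 17.3 ms
        at c_m = 1, matching the validated membrane time constant)
    e_leak : leak reversal, mV (the passive resting potential)
    """

    c_m: float = 1.0
    r_a: float = 100.0
    g_leak: float = 1.0 / 17300.0
    e_leak: float = -79.0

    def __post_init__(self) -> None:
        if self.c_m <= 0 or self.r_a <= 0 or self.g_leak <= 0:
            raise ValueError("c_m, r_a and g_leak must be positive")

    @property
    def r_m(self) -> float:
        """Membrane resistivity, Ohm*cm^2."""
        return 1.0 / self.g_leak


@dataclass
class Segment:
    """One unbranched dendritic stretch (or the merged soma root).

    Lengths/diameters in um; path_distance is measured from the soma
    center to the segment *midpoint* along the tree.
    """

    segment_id: int
    parent_id: int  # -1 marks the root
    tree_label: str  # soma | apical | basal
    length: float
    diameter: float
    path_distance: float = 0.0
    branch_order: int = 0
    # sample points along the segment, used for SWC round-tripping:
    # (x, y, z, radius) rows; synthetic trees use straight-line layouts.
    points: np.ndarray | None = None

    @property
    def volume(self) -> float:
        """Cylinder volume, um^3 (sphere for the soma root)."""
        if self.tree_label == "soma":
            return math.pi * self.diameter**3 / 6.0
        return math.pi * (self.diameter / 2.0) ** 2 * self.length

    @property
    def area(self) -> float:
        """Membrane area, um^2 (cylinder side; sphere for the soma)."""
        if self.tree_label == "soma":
            return math.pi * self.diameter**2
        return math.pi * self.diameter * self.length

    def electrotonic_length(self, passive: PassiveParams) -> float:
        """Dimensionless length / lambda with lambda = sqrt(R_m d / 4 R_a)."""
        return electrotonic_length(self.length, self.diameter, passive)


def space_constant(diameter_um: float, passive: PassiveParams) -> float:
    """Passive length constant lambda in um for a cylinder of given diameter."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    d_cm = diameter_um * 1e-4
    lam_cm = math.sqrt(passive.r_m * d_cm / (4.0 * passive.r_a))
    return lam_cm * 1e4


def electrotonic_length(length_um: float, diameter_um: float,
                        passive: PassiveParams) -> float:
    """length / lambda, reconciling um and the cm-based resistivities."""
    if length_um < 0:
        raise ValueError("length must be non-negative")
    if length_um == 0:
        return 0.0
    return length_um / space_constant(diameter_um, passive)


@dataclass
class Morphology:
    """A validated tree of dendritic segments rooted at the soma."""

    segments: dict[int, Segment]
    children: dict[int, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.children:
            self.children = {sid: [] for sid in self.segments}
            for seg in self.segments.values():
                if seg.parent_id != -1:
                    if seg.parent_id not in self.children:
                        raise SWCError(
                            f"segment {seg.segment_id} references missing "
                            f"parent {seg.parent_id}")
                    self.children[seg.parent_id].append(seg.segment_id)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def root(self) -> Segment:
        roots = [s for s in self.segments.values() if s.parent_id == -1]
        return roots[0]

    def validate(self) -> None:
        roots = [s for s in self.segments.values() if s.parent_id == -1]
        if len(roots) != 1:
            raise SWCError(f"expected exactly one root, found {len(roots)}")
        if roots[0].tree_label != "soma":
            raise SWCError("root segment must be the soma")
        for seg in self.segments.values():
            if seg.parent_id != -1 and seg.parent_id not in self.segments:
                raise SWCError(
                    f"segment {seg.segment_id} references missing parent "
                    f"{seg.parent_id}")
            if seg.tree_label not in _LABEL_TO_TYPE:
                raise SWCError(f"unknown tree label {seg.tree_label!r}")
            if seg.tree_label != "soma" and (seg.length <= 0 or seg.diameter <= 0):
                raise SWCError(f"segment {seg.segment_id} has non-positive size")
        # connectivity / acyclicity: every segment must reach the root
        seen = set()
        stack = [self.root.segment_id]
        while stack:
            sid = stack.pop()
            if sid in seen:
                raise SWCError("cycle detected in morphology")
            seen.add(sid)
            stack.extend(self.children.get(sid, []))
        if seen != set(self.segments):
            raise SWCError("morphology is not connected")

    def dendritic_segments(self, tree: str | None = None) -> list[Segment]:
        out = [s for s in self.segments.values() if s.tree_label != "soma"]
        if tree is not None:
            out = [s for s in out if s.tree_label == tree]
        return sorted(out, key=lambda s: s.segment_id)

    def has_tree(self, tree: str) -> bool:
        return any(s.tree_label == tree for s in self.segments.values())

    def total_length(self, tree: str) -> float:
        return sum(s.length for s in self.dendritic_segments(tree))

    # -- derived tables ----------------------------------------------------
    def morphometrics(self, passive: PassiveParams | None = None) -> pd.DataFrame:
        """Per-segment morphometric table (soma root excluded).

        Columns, in fixed order: segment_id, tree_label, length, diameter,
        volume, path_distance, path_volume, branch_order, electrotonic_length.
        """
        passive = passive or PassiveParams()
        path_vol = self._path_volumes()
        rows = []
        for seg in self.dendritic_segments():
            rows.append({
                "segment_id": seg.segment_id,
                "tree_label": seg.tree_label,
                "length": seg.length,
                "diameter": seg.diameter,
                "volume": seg.volume,
                "path_distance": seg.path_distance,
                "path_volume": path_vol[seg.segment_id],
                "branch_order": seg.branch_order,
                "electrotonic_length": seg.electrotonic_length(passive),
            })
        return pd.DataFrame(rows, columns=[
            "segment_id", "tree_label", "length", "diameter", "volume",
            "path_distance", "path_volume", "branch_order",
            "electrotonic_length"])

    def _path_volumes(self) -> dict[int, float]:
        """Summed segment volumes along the soma-to-segment path (inclusive)."""
        out: dict[int, float] = {}

        def visit(sid: int, acc: float) -> None:
            seg = self.segments[sid]
            v = acc + (0.0 if seg.tree_label == "soma" else seg.volume)
            out[sid] = v
            for c in self.children.get(sid, []):
                visit(c, v)

        visit(self.root.segment_id, 0.0)
        return out


# ---------------------------------------------------------------------------
# SWC reading / writing
# ---------------------------------------------------------------------------

def load_swc(path: str | Path) -> Morphology:
    """Read an SWC reconstruction into a segment tree.

    Consecutive samples of the same type between branch points are merged
    into one dendritic segment whose diameter is the sample-length-weighted
    mean diameter. All soma samples collapse into a single root compartment
    (equivalent-area sphere).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    samples: dict[int, tuple[int, float, float, float, float, int]] = {}
    order: list[int] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCError(f"{path.name}:{lineno}: expected 7 columns, "
                           f"got {len(parts)}")
        try:
            sid = int(parts[0]); typ = int(parts[1])
            x, y, z, r = (float(p) for p in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise SWCError(f"{path.name}:{lineno}: unparsable field ({exc})")
        if typ not in _TYPE_TO_LABEL:
            raise SWCError(f"{path.name}:{lineno}: unknown SWC type code {typ} "
                           f"(supported: {sorted(_TYPE_TO_LABEL)})")
        samples[sid] = (typ, x, y, z, r, parent)
        order.append(sid)
    if not samples:
        raise SWCError(f"{path.name}: no samples")
    return _build_from_samples(samples, order)


def _build_from_samples(samples, order) -> Morphology:
    children: dict[int, list[int]] = {sid: [] for sid in order}
    roots = []
    for sid in order:
        parent = samples[sid][5]
        if parent == -1:
            roots.append(sid)
        else:
            if parent not in samples:
                raise SWCError(f"sample {sid} references missing parent {parent}")
            children[parent].append(sid)
    if len(roots) != 1:
        raise SWCError(f"expected exactly one root sample, found {len(roots)}")

    soma_ids = {sid for sid in order if samples[sid][0] == SWC_SOMA}
    if roots[0] not in soma_ids:
        raise SWCError("root sample must be of soma type (1)")
    # soma: equivalent-area sphere from the sample set
    soma_area = 0.0
    for sid in soma_ids:
        r = samples[sid][4]
        soma_area += 4.0 * math.pi * r * r
    soma_area /= max(len(soma_ids), 1)
    soma_diam = math.sqrt(soma_area / math.pi)
    sx, sy, sz = samples[roots[0]][1:4]

    segments: dict[int, Segment] = {
        0: Segment(0, -1, "soma", soma_diam, soma_diam, 0.0, 0, None)}
    next_id = [1]

    def walk_root() -> None:
        stems = []
        for sid in soma_ids:
            for c in children[sid]:
                if samples[c][0] != SWC_SOMA:
                    stems.append(c)
        for c in stems:
            _walk(c, 0, 0.0, 0)

    def _walk(start: int, parent_seg: int, parent_path: float,
              order_: int) -> None:
        typ = samples[start][0]
        prev = samples[start][5]
        if prev in soma_ids or prev == -1:
            px, py, pz = sx, sy, sz
        else:
            px, py, pz = samples[prev][1:4]
        # anchor radius taken from the run's own first sample so each
        # segment's diameter is computed from its own samples only
        pr = samples[start][4]
        pts = [(px, py, pz, pr)]
        cur = start
        length = 0.0
        wdiam = 0.0
        while True:
            t, x, y, z, r, _ = samples[cur]
            if t != typ:
                raise SWCError(f"type change mid-neurite at sample {cur}")
            step = math.dist((px, py, pz), (x, y, z))
            length += step
            wdiam += step * (r + pr)
            pts.append((x, y, z, r))
            px, py, pz, pr = x, y, z, r
            kids = [c for c in children[cur] if samples[c][0] != SWC_SOMA]
            if len(kids) == 1:
                cur = kids[0]
            else:
                break
        if length <= 0:
            raise SWCError(f"zero-length neurite at sample {start}")
        diameter = wdiam / length
        seg_id = next_id[0]; next_id[0] += 1
        segments[seg_id] = Segment(
            seg_id, parent_seg, _TYPE_TO_LABEL[typ], length, diameter,
            parent_path + length / 2.0, order_, np.asarray(pts))
        child_order = order_ + (1 if len(kids) > 1 else 0)
        for k in kids:
            _walk(k, seg_id, parent_path + length, child_order)

    walk_root()
    return Morphology(segments)


def write_swc(m: Morphology, path: str | Path) -> None:
    """Write a morphology back out as SWC (one sample per stored point)."""
    path = Path(path)
    lines = ["# written by dendrosynergy"]
    soma = m.root
    lines.append(f"1 1 0.0 0.0 0.0 {soma.diameter / 2.0:.6f} -1")
    next_sample = [2]
    tail_sample: dict[int, int] = {soma.segment_id: 1}

    def visit(seg_id: int) -> None:
        seg = m.segments[seg_id]
        if seg.tree_label != "soma":
            typ = _LABEL_TO_TYPE[seg.tree_label]
            pts = seg.points
            if pts is None:  # straight line along +x from parent tail
                raise SWCError(f"segment {seg_id} has no sample points")
            parent_sample = tail_sample[seg.parent_id]
            # first stored point duplicates the parent anchor; skip it
            for (x, y, z, r) in pts[1:]:
                sid = next_sample[0]; next_sample[0] += 1
                lines.append(
                    f"{sid} {typ} {x:.9f} {y:.9f} {z:.9f} {r:.9f} "
                    f"{parent_sample}")
                parent_sample = sid
            tail_sample[seg_id] = parent_sample
        for c in m.children.get(seg_id, []):
            visit(c)

    visit(soma.segment_id)
    path.write_text("\n".join(lines) + "\n")
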