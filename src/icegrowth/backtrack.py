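"""Back-tracking of frozen waters through their polymer-contact history.

Waters constituting a chosen frozen ice layer are preselected at the end
of the analysed span and the trajectory is traversed backwards over a
window (default 20 ns at 10 ps spacing). Every water-polymer hydrogen
bond along the way is recorded and each water is classified by whether
it travelled via the polymer at all (``via_pg``), which polymer segment
unit (L13/L14/D/T) it contacted most, and the maximum number of
simultaneous bonds it formed with any one polymer molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Topology, Trajectory
from .hbond import detect_hbonds, _polymer_water_pairs
from .phase import PhaseLabels

SEGMENT_ORDER = ("L13", "L14", "D", "T")


@dataclass
class BacktrackRecord:
    """Classification of one frozen water's history."""

    water_id: int
    via_pg: bool
    segment: str                      # argmax contact segment or NONE
    max_multiplicity: int
    segment_frames: dict = field(default_factory=dict)
    final_xy: tuple = (np.nan, np.nan)
    layer: int = -1


@dataclass
class LayerSummary:
    """Per-layer pooled classification fractions."""

    layer: int
    n_waters: int
    frac_via_pg: float
    segment_fractions: dict           # among via_pg waters
    multiplicity_counts: dict


def select_layer(labels: PhaseLabels, traj: Trajectory, topo: Topology,
                 layer_index: int | None = None,
                 z_window: tuple[float, float] | None = None,
                 lattice=None, frame: int = -1) -> set[int]:
    """Water molecule ids of one frozen layer in the final analysed frame.

    Either a lattice ``layer_index`` (with the generating lattice for the
    z bounds) or an explicit ``z_window`` selects the slab region; every
    water inside it must be ICE-labelled, otherwise the layer is not
    fully frozen and an error is raised.
    """
    if z_window is None:
        if lattice is None or layer_index is None:
            raise ValueError("pass z_window or (layer_index, lattice)")
        lo, up = lattice.layer_z(layer_index)
        z_window = (lo - lattice.c / 16.0, up + lattice.c / 16.0)
    fi = frame % labels.n_frames
    o_idx = topo.water_oxygen_idx
    z = traj[fi].positions[o_idx, 2]
    inside = (z >= z_window[0]) & (z <= z_window[1])
    if not inside.any():
        raise ValueError(f"no water inside z window {z_window}")
    if not labels.ice[fi, inside].all():
        n_liq = int(np.sum(~labels.ice[fi, inside]))
        raise ValueError(f"layer not fully frozen: {n_liq} liquid waters "
                         f"inside z window {z_window}")
    return set(int(m) for m in topo.molecule_ids[o_idx][inside])


def backtrack_classify(traj: Trajectory, topo: Topology, selection,
                       window: float = 20000.0, stride: int = 1,
                       d_max: float = 0.35, angle_min: float = 150.0,
                       end_frame: int = -1,
                       layer: int = -1) -> list[BacktrackRecord]:
    """Classify each selected water's polymer contacts over the window.

    Frames are iterated backwards from ``end_frame`` over ``window`` ps at
    ``stride`` frames. Segment attribution is the majority of
    contact frames, ties broken by the most recent contact; multiplicity
    is the maximum simultaneous bond count with any one polymer molecule.
    """
    selection = sorted(int(s) for s in selection)
    if not selection:
        raise ValueError("empty selection")
    times = traj.times
    fi_end = end_frame % traj.n_frames
    t_end = times[fi_end]
    if t_end - times[0] + 1e-9 < window:
        raise ValueError("window extends beyond the trajectory span")
    frame_ids = list(range(fi_end, -1, -stride))
    frame_ids = [f for f in frame_ids if t_end - times[f] <= window + 1e-9]

    sel_set = set(selection)
    seg_frames = {w: {} for w in selection}
    last_contact = {w: {} for w in selection}
    max_mult = {w: 0 for w in selection}
    for f in frame_ids:
        rec = detect_hbonds(traj[f], topo, traj.box, d_max, angle_min,
                            frame_index=f, polymer_only=True)
        rec = _polymer_water_pairs(rec, topo)
        if len(rec) == 0:
            continue
        rec = rec[rec["water_mol"].isin(sel_set)]
        if len(rec) == 0:
            continue
        for (w, _pm), grp in rec.groupby(["water_mol", "polymer_mol"]):
            w = int(w)
            max_mult[w] = max(max_mult[w], len(grp))
        for w, grp in rec.groupby("water_mol"):
            w = int(w)
            for seg in set(grp["segment"]):
                seg_frames[w][seg] = seg_frames[w].get(seg, 0) + 1
                last_contact[w][seg] = max(last_contact[w].get(seg, -1), f)

    o_idx = topo.water_oxygen_idx
    mol_of_o = topo.molecule_ids[o_idx]
    out = []
    for w in selection:
        counts = seg_frames[w]
        via = sum(counts.values()) > 0
        if via:
            best = max(counts, key=lambda s: (counts[s], last_contact[w][s]))
        else:
            best = "NONE"
        orow = o_idx[mol_of_o == w][0]
        xy = traj[fi_end].positions[orow, :2]
        out.append(BacktrackRecord(w, via, best, max_mult[w], dict(counts),
                                   (float(xy[0]), float(xy[1])), layer))
    return out


def records_to_frame(records: list[BacktrackRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.water_id, r.layer, r.via_pg, r.segment, r.max_multiplicity,
          r.final_xy[0], r.final_xy[1]) for r in records],
        columns=["water_id", "layer", "via_pg", "segment",
                 "max_multiplicity", "x", "y"])


def summarize_layers(records: list[BacktrackRecord]) -> list[LayerSummary]:
    """Per-layer fractions of via-polymer travel, segments, multiplicity."""
    if not records:
        raise ValueError("no back-tracking records")
    by_layer: dict[int, list[BacktrackRecord]] = {}
    for r in records:
        by_layer.setdefault(r.layer, []).append(r)
    out = []
    for layer in sorted(by_layer):
        recs = by_layer[layer]
        n = len(recs)
        via = [r for r in recs if r.via_pg]
        segf = {}
        if via:
            for s in SEGMENT_ORDER:
                segf[s] = sum(1 for r in via if r.segment == s) / len(via)
        mult: dict[int, int] = {}
        for r in via:
            mult[r.max_multiplicity] = mult.get(r.max_multiplicity, 0) + 1
        out.append(LayerSummary(layer, n, len(via) / n, segf, mult))
    return out


def summaries_to_frame(summaries: list[LayerSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"layer": s.layer, "n_waters": s.n_waters,
               "frac_via_pg": s.frac_via_pg}
        for seg in SEGMENT_ORDER:
            row[f"frac_{seg}"] = s.segment_fractions.get(seg, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
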