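"""Geometric hydrogen-bond detection and statistics.

A hydrogen bond is counted when the donor...acceptor heavy-atom distance
is at most ``d_max`` (0.35 nm) and the donor-H...acceptor angle at the
hydrogen is at least ``angle_min`` (150 degrees), under periodic boundary
conditions. Both water->polymer and polymer->water directions count.
Lifetimes use the continuous-survival definition (a bond present at an
origin survives to lag t if present in all intervening frames, tolerating
gaps up to ``allow_gap`` frames) and the scalar lifetime is the integral
of the survival curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (POLYMER, WATER, Frame, SimulationBox, Topology,
                   Trajectory, cross_pairs_within)

HBOND_COLUMNS = ["frame", "donor_id", "hydrogen_id", "acceptor_id",
                 "donor_mol", "acceptor_mol", "segment"]


@dataclass
class MultiplicityHistogram:
    """Distribution of simultaneous water-polymer bond multiplicity.

    Fractions are over (frame, water, polymer-molecule) observations with
    at least one bond; ``proportion_multiple`` pools m >= 2.
    """

    fractions: dict
    counts: dict
    n_observations: int

    @property
    def proportion_multiple(self) -> float:
        return sum(v for k, v in self.fractions.items() if k != 1)

    def to_frame(self) -> pd.DataFrame:
        keys = sorted(self.fractions, key=lambda k: (isinstance(k, str), k))
        return pd.DataFrame({"multiplicity": keys,
                             "fraction": [self.fractions[k] for k in keys],
                             "count": [self.counts[k] for k in keys]})


def detect_hbonds(frame: Frame, topo: Topology, box: SimulationBox,
                  d_max: float = 0.35, angle_min: float = 150.0,
                  frame_index: int = 0,
                  polymer_only: bool = False) -> pd.DataFrame:
    """All hydrogen bonds in one frame as a record table.

    ``polymer_only`` restricts to bonds with exactly one polymer side
    (the scope every polymer-water statistic uses). The ``segment``
    column carries the polymer unit involved, or NONE.
    """
    don = np.where(topo.donor)[0]
    acc = np.where(topo.acceptor)[0]
    if len(don) == 0 or len(acc) == 0:
        return pd.DataFrame(columns=HBOND_COLUMNS)
    pos = frame.positions
    pairs = cross_pairs_within(pos[don], pos[acc], box, d_max)
    cos_min = np.cos(np.deg2rad(angle_min))
    rec = []
    for di, ai in pairs:
        d_row, a_row = don[di], acc[ai]
        if topo.molecule_ids[d_row] == topo.molecule_ids[a_row]:
            continue
        if polymer_only:
            kd, ka = topo.kinds[d_row], topo.kinds[a_row]
            if not ((kd == POLYMER) ^ (ka == POLYMER)):
                continue
            if not ((kd == WATER) or (ka == WATER)):
                continue
        for h_row in np.where(topo.parent == topo.ids[d_row])[0]:
            v_d = box.min_image(pos[d_row] - pos[h_row])
            v_a = box.min_image(pos[a_row] - pos[h_row])
            cosang = float(v_d @ v_a /
                           (np.linalg.norm(v_d) * np.linalg.norm(v_a)))
            # angle >= angle_min <=> cos(angle) <= cos(angle_min)
            if cosang <= cos_min:
                seg = "NONE"
                if topo.kinds[d_row] == POLYMER:
                    seg = str(topo.segments[d_row])
                elif topo.kinds[a_row] == POLYMER:
                    seg = str(topo.segments[a_row])
                rec.append((frame_index, int(topo.ids[d_row]),
                            int(topo.ids[h_row]), int(topo.ids[a_row]),
                            int(topo.molecule_ids[d_row]),
                            int(topo.molecule_ids[a_row]), seg))
    return pd.DataFrame(rec, columns=HBOND_COLUMNS)


def detect_hbonds_trajectory(traj: Trajectory, topo: Topology,
                             d_max: float = 0.35, angle_min: float = 150.0,
                             polymer_only: bool = False,
                             frame_indices=None) -> pd.DataFrame:
    frames = range(traj.n_frames) if frame_indices is None else frame_indices
    parts = [detect_hbonds(traj[i], topo, traj.box, d_max, angle_min,
                           frame_index=i, polymer_only=polymer_only)
             for i in frames]
    return pd.concat(parts, ignore_index=True) if parts else \
        pd.DataFrame(columns=HBOND_COLUMNS)


def _polymer_water_pairs(records: pd.DataFrame, topo: Topology) -> pd.DataFrame:
    """Annotate records with (water_mol, polymer_mol); drops other bonds."""
    kind_of_mol = {}
    for m, k in zip(topo.molecule_ids, topo.kinds):
        kind_of_mol[int(m)] = str(k)
    dk = records["donor_mol"].map(kind_of_mol)
    ak = records["acceptor_mol"].map(kind_of_mol)
    keep = ((dk == POLYMER) & (ak == WATER)) | ((dk == WATER) & (ak == POLYMER))
    out = records[keep].copy()
    dk = dk[keep]
    out["water_mol"] = np.where(dk == WATER, out["donor_mol"],
                                out["acceptor_mol"])
    out["polymer_mol"] = np.where(dk == POLYMER, out["donor_mol"],
                                  out["acceptor_mol"])
    return out


def hbond_series(traj: Trajectory, topo: Topology, labels=None,
                 partner: str = "water", d_max: float = 0.35,
                 angle_min: float = 150.0) -> pd.DataFrame:
    """Per-frame polymer H-bond counts with water/ice/liquid partners.

    Emits both the system total and the per-polymer average (the paper's
    per-figure normalisation is ambiguous, so both are reported).
    """
    if partner not in ("water", "ice", "liquid"):
        raise ValueError("partner must be water, ice or liquid")
    if partner != "water" and labels is None:
        raise ValueError(f"partner={partner!r} requires phase labels")
    if labels is not None and labels.n_frames != traj.n_frames:
        raise ValueError("labels do not cover the trajectory")
    n_poly = len(set(topo.molecule_ids[topo.polymer_idx].tolist()))
    if n_poly == 0:
        raise ValueError("no polymer present")
    wid_index = {int(w): j for j, w in enumerate(
        topo.molecule_ids[topo.water_oxygen_idx])}
    rows = []
    for i in range(traj.n_frames):
        rec = detect_hbonds(traj[i], topo, traj.box, d_max, angle_min,
                            frame_index=i, polymer_only=True)
        rec = _polymer_water_pairs(rec, topo)
        if partner == "water" or len(rec) == 0:
            n = len(rec)
        else:
            want_ice = partner == "ice"
            cols = rec["water_mol"].map(wid_index).to_numpy()
            is_ice = labels.ice[i, cols]
            n = int(np.sum(is_ice == want_ice))
        rows.append((traj[i].time, n, n / n_poly))
    return pd.DataFrame(rows, columns=["time", "n_bonds", "n_per_polymer"])


def _bond_runs(frame_sets: list[set], allow_gap: int) -> list[int]:
    """Run lengths (frames) of each bond key, merging gaps <= allow_gap."""
    seen: dict[tuple, list[int]] = {}
    for i, s in enumerate(frame_sets):
        for key in s:
            seen.setdefault(key, []).append(i)
    runs = []
    for key, idx in seen.items():
        start = prev = idx[0]
        for i in idx[1:]:
            if i - prev > allow_gap + 1:
                runs.append(prev - start + 1)
                start = i
            prev = i
        runs.append(prev - start + 1)
    return runs


def hbond_lifetime(traj: Trajectory, topo: Topology,
                   pair_scope: str = "all", allow_gap: int = 1,
                   d_max: float = 0.35, angle_min: float = 150.0):
    """Continuous-survival curve S(t) and lifetime (ps) of H-bonds.

    ``pair_scope`` is "all", "polymer-water" or "water-water". S(t) is the
    fraction of bond formation events still intact after lag t; the
    lifetime is the step-function integral of S to the last lag (which
    equals the mean bonded duration).
    """
    if traj.n_frames < 10:
        raise ValueError("need at least 10 frames for lifetime statistics")
    if pair_scope not in ("all", "polymer-water", "water-water"):
        raise ValueError(f"unknown pair scope {pair_scope!r}")
    frame_sets = []
    for i in range(traj.n_frames):
        rec = detect_hbonds(traj[i], topo, traj.box, d_max, angle_min,
                            frame_index=i,
                            polymer_only=(pair_scope == "polymer-water"))
        if pair_scope == "water-water":
            kind_of_mol = dict(zip(topo.molecule_ids.astype(int),
                                   topo.kinds))
            keep = rec["donor_mol"].map(kind_of_mol).eq(WATER) & \
                rec["acceptor_mol"].map(kind_of_mol).eq(WATER)
            rec = rec[keep]
        frame_sets.append(set(zip(rec["donor_id"], rec["hydrogen_id"],
                                  rec["acceptor_id"])))
    runs = np.array(_bond_runs(frame_sets, allow_gap))
    if len(runs) == 0:
        raise ValueError("no hydrogen bonds found")
    dt = float(np.median(np.diff(traj.times)))
    lags = np.arange(int(runs.max()) + 1)
    # survival past lag k, one origin per bond formation event
    s = np.array([np.mean(runs > k) for k in lags])
    curve = pd.DataFrame({"lag": lags * dt, "survival": s})
    # step-function integral of S(t); equals dt * mean run length
    lifetime = float(dt * np.sum(s))
    return curve, lifetime


def multiplicity(traj: Trajectory, topo: Topology, d_max: float = 0.35,
                 angle_min: float = 150.0) -> MultiplicityHistogram:
    """Histogram of simultaneous bonds per (water, polymer) pair.

    m counts distinct simultaneous H-bonds (either donation direction)
    between one water molecule and one polymer molecule in one frame,
    pooled over frames; reported as fractions of singly and multiply
    (double/triple/quadruple) bonded waters.
    """
    if len(topo.polymer_idx) == 0:
        raise ValueError("no polymer present")
    rec = detect_hbonds_trajectory(traj, topo, d_max, angle_min,
                                   polymer_only=True)
    rec = _polymer_water_pairs(rec, topo)
    counts: dict = {1: 0, 2: 0, 3: 0, "4+": 0}
    if len(rec):
        grouped = rec.groupby(["frame", "water_mol", "polymer_mol"]).size()
        for m in grouped:
            counts[m if m < 4 else "4+"] += 1
    n = sum(counts.values())
    fractions = {k: (v / n if n else 0.0) for k, v in counts.items()}
    return MultiplicityHistogram(fractions, counts, n)
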