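"""Ice/liquid classification, front-height tracking and step detection.

Waters are classified with degree-6 bond-orientational connection
counting (ten Wolde-Frenkel style): per oxygen a complex q6 vector is
accumulated over neighbours within ``r_cut``, normalised, and a neighbour
pair counts as *connected* when the real part of the normalised inner
product exceeds ``q_threshold``. An oxygen with at least
``min_connections`` connected neighbours is ICE. The front height h(t) is
the top of the ice region that is z-connected to the seed slab, and
stepwise growth is extracted with a piecewise-constant change-point fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import sph_harm_y

from .core import SimulationBox, Topology, Trajectory, neighbor_lists

L_ORDER = 6


@dataclass
class PhaseLabels:
    """Per-water, per-frame phase assignment.

    ``ice`` is a (n_frames, n_waters) boolean array aligned with
    ``water_ids`` (water molecule ids in file order); ``n_connections``
    holds the connected-neighbour counts behind each call.
    """

    water_ids: np.ndarray
    times: np.ndarray
    ice: np.ndarray
    n_connections: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.ice.shape[0]

    def frame_ice_fraction(self) -> np.ndarray:
        return self.ice.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rec = []
        for t in range(self.n_frames):
            for j, w in enumerate(self.water_ids):
                rec.append((self.times[t], int(w),
                            "ICE" if self.ice[t, j] else "LIQUID",
                            int(self.n_connections[t, j])))
        return pd.DataFrame(rec, columns=["time", "water_id", "label",
                                          "n_connections"])


@dataclass
class GrowthTrace:
    """Front height series and detected growth steps."""

    times: np.ndarray
    h: np.ndarray
    layers: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    steps: list = field(default_factory=list)   # (time ps, rise nm)


def q6_vectors(oxygens: np.ndarray, box: SimulationBox, r_cut: float):
    """Normalised complex q6 vector and neighbour list per oxygen.

    Oxygens with no neighbours get a zero vector.
    """
    nbrs = neighbor_lists(oxygens, box, r_cut)
    n = len(oxygens)
    q = np.zeros((n, 2 * L_ORDER + 1), dtype=complex)
    for i in range(n):
        js = nbrs[i]
        if len(js) == 0:
            continue
        d = box.min_image(oxygens[js] - oxygens[i])
        r = np.linalg.norm(d, axis=1)
        theta = np.arccos(np.clip(d[:, 2] / r, -1.0, 1.0))
        phi = np.arctan2(d[:, 1], d[:, 0])
        for mi, m in enumerate(range(-L_ORDER, L_ORDER + 1)):
            q[i, mi] = np.mean(sph_harm_y(L_ORDER, m, theta, phi))
        norm = np.linalg.norm(q[i])
        if norm > 0:
            q[i] /= norm
    return q, nbrs


def classify_frame(oxygens: np.ndarray, box: SimulationBox,
                   r_cut: float = 0.35, q_threshold: float = 0.7,
                   min_connections: int = 3):
    """(ice boolean, connection count) per oxygen for one frame."""
    if len(oxygens) < 2:
        raise ValueError("need at least two waters to classify phase")
    q, nbrs = q6_vectors(oxygens, box, r_cut)
    ncon = np.zeros(len(oxygens), dtype=int)
    for i in range(len(oxygens)):
        js = nbrs[i]
        if len(js) == 0:
            continue
        dots = np.real(q[js] @ np.conj(q[i]))
        ncon[i] = int(np.sum(dots > q_threshold))
    return ncon >= min_connections, ncon


def classify_phase(traj: Trajectory, topo: Topology, r_cut: float = 0.35,
                   q_threshold: float = 0.7,
                   min_connections: int = 3) -> PhaseLabels:
    """Label every water ICE or LIQUID in every frame."""
    o_idx = topo.water_oxygen_idx
    if len(o_idx) < 2:
        raise ValueError("need at least two waters to classify phase")
    n = len(o_idx)
    ice = np.zeros((traj.n_frames, n), dtype=bool)
    ncon = np.zeros((traj.n_frames, n), dtype=int)
    for t, fr in enumerate(traj):
        ice[t], ncon[t] = classify_frame(fr.positions[o_idx], traj.box,
                                         r_cut, q_threshold, min_connections)
    return PhaseLabels(topo.molecule_ids[o_idx], traj.times, ice, ncon)


def front_height(labels: PhaseLabels, traj: Trajectory, topo: Topology,
                 bin_width: float = 0.05, occupancy: float = 0.5,
                 gap_tol: float = 0.45, min_count: int = 3,
                 layer_spacing: float | None = None) -> GrowthTrace:
    """h(t): top of the seed-connected ice slab along z.

    A z-bin qualifies when it holds at least ``min_count`` waters and its
    ice fraction is >= ``occupancy`` (an occupancy over one or two waters
    is not evidence of a layer); qualifying bins are chained bottom-up
    allowing vertical gaps up to ``gap_tol`` (the empty space inside an
    ice bilayer), and h is the mean oxygen z in the highest chained bin.
    Detached ice clusters floating higher up are excluded by the chaining
    rule.
    """
    o_idx = topo.water_oxygen_idx
    zmax = traj.box.lengths[2]
    edges = np.arange(0.0, zmax + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hs = np.empty(labels.n_frames)
    layers = np.zeros(labels.n_frames, dtype=int)
    spacing = layer_spacing
    for t in range(labels.n_frames):
        z = traj[t].positions[o_idx, 2]
        which = np.digitize(z, edges) - 1
        which = np.clip(which, 0, len(centers) - 1)
        icy = []
        for b in np.unique(which):
            sel = which == b
            if sel.sum() >= min_count and \
                    np.mean(labels.ice[t, sel]) >= occupancy:
                icy.append(b)
        if not icy:
            raise ValueError(f"no ice found at frame {t}")
        icy = np.array(icy)
        if centers[icy[0]] > 5 * gap_tol:
            raise ValueError(
                f"no ice connected to the bottom boundary at frame {t}")
        # chain bins from the seed upward
        top = icy[0]
        for b in icy[1:]:
            if centers[b] - centers[top] <= gap_tol:
                top = b
            else:
                break
        in_top = (which == top) & labels.ice[t]
        hs[t] = float(np.mean(z[in_top]))
        if spacing:
            layers[t] = int(round(hs[t] / spacing))
    return GrowthTrace(labels.times, hs, layers)


def _sse(y: np.ndarray) -> float:
    return float(np.sum((y - y.mean()) ** 2)) if len(y) else 0.0


def _split_segment(y, lo, hi, min_rise, min_len):
    """Best change point in y[lo:hi), or None."""
    best, best_cost = None, _sse(y[lo:hi])
    for k in range(lo + min_len, hi - min_len + 1):
        c = _sse(y[lo:k]) + _sse(y[k:hi])
        if c < best_cost - 1e-12:
            best, best_cost = k, c
    if best is None:
        return None
    if abs(y[best:hi].mean() - y[lo:best].mean()) < min_rise:
        return None
    return best

def detect_steps(trace: GrowthTrace, min_rise: float = 0.1,
                 min_len: int = 2) -> list[tuple[float, float]]:
    """Piecewise-constant change-point fit of h(t).

    Returns (time of rise midpoint, rise) pairs; candidate change points
    come from recursive binary segmentation and are kept only when the
    plateau-mean change reaches ``min_rise`` (smaller changes are merged
    into their neighbours). The fitted steps are written back onto
    ``trace.steps``.
    """
    y = np.asarray(trace.h, dtype=float)
    t = np.asarray(trace.times, dtype=float)
    if len(y) < 3:
        raise ValueError("height series too short for step detection")
    bounds = [0, len(y)]
    stack = [(0, len(y))]
    while stack:
        lo, hi = stack.pop()
        k = _split_segment(y, lo, hi, min_rise, min_len)
        if k is not None:
            bounds.append(k)
            stack.extend([(lo, k), (k, hi)])
    bounds = sorted(set(bounds))
    # merge sub-threshold plateau changes into neighbours
    means = [y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    keep = [bounds[0]]
    for i in range(1, len(bounds) - 1):
        if abs(means[i] - means[i - 1]) >= min_rise:
            keep.append(bounds[i])
        else:
            means[i] = y[keep[-1]:bounds[i + 1]].mean()
    keep.append(bounds[-1])
    steps = []
    for a, b in zip(keep[1:-1], keep[2:]):
        prev = keep[keep.index(a) - 1]
        rise = y[a:b].mean() - y[prev:a].mean()
        if rise >= min_rise:
            steps.append((float(0.5 * (t[a - 1] + t[a])), float(rise)))
    trace.steps = steps
    return steps
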