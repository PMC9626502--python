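"""Iso-configurational mobility, shell-resolved diffusion, lateral tracking.

Dynamical propensity (DP) of a water molecule is its squared displacement
at a lag t*, averaged over an iso-configurational ensemble: M runs that
share the initial configuration but differ in their dynamical histories.
The lowest 5% of the DP distribution is the most-immobile (MI) set, the
top 5% the most-mobile (MM) set. Shell diffusion resolves the water
diffusion coefficient by distance from the polymer; lateral tracking
labels the polymer centre-of-mass path into dwell and migration segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Topology, Trajectory, unwrap_positions


@dataclass
class PropensityField:
    """Per-water dynamical propensity with MI/MM 5% tails."""

    water_ids: np.ndarray
    dp: np.ndarray          # nm^2 at t_star
    t_star: float
    M: int
    tail_fraction: float = 0.05
    mi: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    mm: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self):
        k = int(round(self.tail_fraction * len(self.water_ids)))
        # stable tie-break on (dp, id) keeps the sets deterministic
        order = np.lexsort((self.water_ids, self.dp))
        self.mi = np.sort(self.water_ids[order[:k]])
        self.mm = np.sort(self.water_ids[order[len(order) - k:]])

    def to_frame(self) -> pd.DataFrame:
        cls = np.full(len(self.water_ids), "", dtype=object)
        cls[np.isin(self.water_ids, self.mi)] = "MI"
        cls[np.isin(self.water_ids, self.mm)] = "MM"
        return pd.DataFrame({"water_id": self.water_ids, "dp": self.dp,
                             "class": cls})


@dataclass
class ShellDiffusionResult:
    """Per-shell diffusion coefficients around the polymer."""

    shell_edges: np.ndarray            # outer radii, nm
    diffusion: np.ndarray              # nm^2/ps (NaN where shell empty)
    counts: np.ndarray                 # resident (molecule, origin) samples
    msd_curves: list[pd.DataFrame]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"shell_outer_nm": self.shell_edges,
                             "D_nm2_per_ps": self.diffusion,
                             "D_nm2_per_ns": self.diffusion * 1e3,
                             "count": self.counts})


@dataclass
class MiNearResult:
    """Fractions relating the MI set to the polymer neighbourhood."""

    defined: bool
    frac_mi_near: float = np.nan    # MI molecules within r of polymer
    frac_near_mi: float = np.nan    # near-polymer molecules that are MI
    n_mi: int = 0
    n_near: int = 0


def propensity(ensemble: list[Trajectory], topo: Topology,
               t_star: float = 100.0,
               tail_fraction: float = 0.05) -> PropensityField:
    """Ensemble-mean squared displacement per water at lag t_star.

    All trajectories must share the frame-0 configuration (checked to
    1e-6 nm); displacements are PBC-unwrapped before squaring.
    """
    if len(ensemble) < 1:
        raise ValueError("empty ensemble")
    ref = ensemble[0][0].positions
    for k, tr in enumerate(ensemble[1:], start=1):
        if not np.allclose(tr[0].positions, ref, atol=1e-6):
            raise ValueError(f"run {k} does not share the initial configuration")
    o_idx = topo.water_oxygen_idx
    dp = np.zeros(len(o_idx))
    for tr in ensemble:
        ti = int(np.argmin(np.abs(tr.times - tr.times[0] - t_star)))
        unwrapped = unwrap_positions(tr, o_idx)
        disp = unwrapped[ti] - unwrapped[0]
        dp += np.sum(disp ** 2, axis=1)
    dp /= len(ensemble)
    return PropensityField(topo.molecule_ids[o_idx], dp, t_star,
                           len(ensemble), tail_fraction)


def _min_dist_to_polymer(positions, o_idx, poly_idx, box):
    if len(poly_idx) == 0:
        return None
    d = box.min_image(positions[o_idx][:, None, :] -
                      positions[poly_idx][None, :, :])
    return np.linalg.norm(d, axis=2).min(axis=1)


def mi_fraction_near(field: PropensityField, traj: Trajectory,
                     topo: Topology, r: float = 0.5) -> MiNearResult:
    """Overlap between the MI set and the polymer's r-neighbourhood.

    Both normalisations are reported: the fraction of MI waters whose
    frame-0 minimum heavy-atom distance to the polymer is <= r, and the
    fraction of near-polymer waters that are MI.
    """
    poly = topo.polymer_heavy_idx
    if len(poly) == 0:
        return MiNearResult(defined=False)
    o_idx = topo.water_oxygen_idx
    dmin = _min_dist_to_polymer(traj[0].positions, o_idx, poly, traj.box)
    near = topo.molecule_ids[o_idx][dmin <= r]
    mi = field.mi
    n_mi, n_near = len(mi), len(near)
    if n_mi == 0 or n_near == 0:
        return MiNearResult(defined=False, n_mi=n_mi, n_near=n_near)
    inter = len(np.intersect1d(mi, near))
    return MiNearResult(True, inter / n_mi, inter / n_near, n_mi, n_near)


def shell_diffusion(traj: Trajectory, topo: Topology,
                    shells=(0.5, 1.0, 2.0),
                    fit_window: tuple[float, float] = (10.0, 50.0),
                    origin_stride: int = 10,
                    residence: bool = True) -> ShellDiffusionResult:
    """Diffusion coefficient of water by distance shell from the polymer.

    Molecules are assigned to the innermost shell whose outer radius
    covers their minimum O-to-polymer-heavy-atom distance at each time
    origin; with ``residence`` (the default) only molecules staying in
    that shell for the whole fit window contribute, which keeps mobility
    populations from mixing but slightly censors the largest excursions.
    D is the slope of a linear MSD fit over ``fit_window`` (ps) divided
    by 6, in nm^2/ps.
    """
    shells = np.asarray(sorted(shells), dtype=float)
    poly = topo.polymer_heavy_idx
    if len(poly) == 0:
        raise ValueError("no polymer present")
    o_idx = topo.water_oxygen_idx
    times = traj.times - traj.times[0]
    dt = float(np.median(np.diff(times)))
    win_frames = int(round(fit_window[1] / dt))
    if win_frames >= traj.n_frames:
        raise ValueError("trajectory shorter than the MSD fit window")
    unwrapped = unwrap_positions(traj, o_idx)
    dists = np.stack([_min_dist_to_polymer(traj[t].positions, o_idx, poly,
                                           traj.box)
                      for t in range(traj.n_frames)])
    shell_of = np.searchsorted(shells, dists)   # per frame, per molecule
    lags = np.arange(win_frames + 1)
    sums = np.zeros((len(shells), len(lags)))
    counts = np.zeros(len(shells))
    nobs = np.zeros((len(shells), len(lags)))
    origins = range(0, traj.n_frames - win_frames, origin_stride)
    for t0 in origins:
        s0 = shell_of[t0]
        if residence:
            resident = np.all(shell_of[t0:t0 + win_frames + 1] == s0[None, :],
                              axis=0)
        else:
            resident = np.ones(len(s0), dtype=bool)
        for s in range(len(shells)):
            sel = resident & (s0 == s)
            if not sel.any():
                continue
            counts[s] += sel.sum()
            disp = unwrapped[t0:t0 + win_frames + 1, sel, :] - \
                unwrapped[t0, sel, :]
            sums[s] += np.sum(disp ** 2, axis=(1, 2))
            nobs[s] += sel.sum()
    diffusion = np.full(len(shells), np.nan)
    curves = []
    tau = lags * dt
    fit = (tau >= fit_window[0]) & (tau <= fit_window[1])
    for s in range(len(shells)):
        if counts[s] == 0:
            curves.append(pd.DataFrame({"tau": tau, "msd": np.nan}))
            continue
        msd = sums[s] / nobs[s]
        curves.append(pd.DataFrame({"tau": tau, "msd": msd}))
        slope = np.polyfit(tau[fit], msd[fit], 1)[0]
        diffusion[s] = max(slope / 6.0, 0.0)
    return ShellDiffusionResult(shells, diffusion, counts.astype(int), curves)


@dataclass
class LateralTrack:
    """Unwrapped polymer COM path with dwell/migration labels."""

    times: np.ndarray
    xy: np.ndarray                 # unwrapped (n_frames, 2)
    labels: np.ndarray             # "DWELL" / "MIGRATE" per frame
    segments: list                 # (label, t_start, t_end)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "x": self.xy[:, 0],
                             "y": self.xy[:, 1], "state": self.labels})


def lateral_track(traj: Trajectory, topo: Topology,
                  dwell_window: float = 100.0,
                  dwell_rms: float = 0.1,
                  polymer_mol: int | None = None) -> LateralTrack:
    """Label the polymer's lateral (x, y) motion into dwell and migration.

    A frame is DWELL when the rolling RMS displacement of the unwrapped
    centre of mass about its window mean is below ``dwell_rms`` over
    ``dwell_window`` ps, else MIGRATE; equal consecutive labels are
    merged into segments.
    """
    poly = topo.polymer_idx
    if len(poly) == 0:
        raise ValueError("no polymer present")
    if polymer_mol is not None:
        poly = poly[topo.molecule_ids[poly] == polymer_mol]
    unwrapped = unwrap_positions(traj, poly)
    w = topo.masses[poly]
    com = np.einsum("tij,i->tj", unwrapped, w) / w.sum()
    xy = com[:, :2]
    times = traj.times
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    half = max(1, int(round(dwell_window / dt / 2)))
    labels = np.empty(len(times), dtype=object)
    for i in range(len(times)):
        lo, hi = max(0, i - half), min(len(times), i + half + 1)
        seg = xy[lo:hi]
        rms = float(np.sqrt(np.mean(np.sum((seg - seg.mean(axis=0)) ** 2,
                                           axis=1))))
        labels[i] = "DWELL" if rms < dwell_rms else "MIGRATE"
    segments = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segments.append((str(labels[start]), float(times[start]),
                             float(times[i - 1])))
            start = i
    return LateralTrack(times, xy, labels, segments)
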