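"""Mass-density fields and quasi-liquid-layer (QLL) thickness.

The QLL is the disordered-but-structured water between crystalline ice
and bulk liquid at the growth front. Its thickness is estimated from the
z-density profile: crystalline ice shows layering oscillations whose
local amplitude decays to zero across the QLL. The local amplitude is
measured by demodulating the profile at the layer period over a rolling
one-period window; boundary crossings are located at 50% and 10% of the
bulk-ice amplitude (robustly away from the noisy extremes) and linearly
extrapolated to the full-amplitude and zero-amplitude levels, so that for
a linear amplitude decay the estimate equals the full transition width.
An alternative route takes phase labels instead of a density profile and
uses the 85%/15% crossings of the ice-fraction profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import AMU_PER_NM3_TO_G_CM3, Topology, Trajectory


@dataclass
class DensityProfile1D:
    """z profile of mass density (g/cm^3), frame- and xy-averaged."""

    z: np.ndarray
    density: np.ndarray
    bin_width: float
    slab_area: float       # nm^2
    n_frames: int

    @property
    def total_mass(self) -> float:
        """amu accounted for by the profile."""
        vol = self.slab_area * self.bin_width
        return float(np.sum(self.density) * vol / AMU_PER_NM3_TO_G_CM3)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z": self.z, "density": self.density})


@dataclass
class DensityMap2D:
    """(x, z) mass-density grid (g/cm^3), y- and frame-averaged."""

    x: np.ndarray
    z: np.ndarray
    density: np.ndarray    # shape (len(x), len(z))
    bin_x: float
    bin_z: float
    depth: float           # nm averaged over (the y extent)
    n_frames: int
    cap: float = 2.0       # g/cm^3 rendering cap used by the figures

    @property
    def total_mass(self) -> float:
        vol = self.bin_x * self.bin_z * self.depth
        return float(np.sum(self.density) * vol / AMU_PER_NM3_TO_G_CM3)


@dataclass
class QllEstimate:
    """Quasi-liquid-layer boundaries and thickness in nm."""

    z_ice: float
    z_liq: float
    per_frame: pd.DataFrame | None = None

    @property
    def thickness(self) -> float:
        return max(0.0, self.z_liq - self.z_ice)


def _selection_indices(topo: Topology, species: str) -> np.ndarray:
    if species == "water":
        return np.where(topo.kinds == "WATER")[0]
    if species == "polymer":
        return np.where(topo.kinds == "POLYMER")[0]
    if species == "all":
        return np.arange(topo.n_atoms)
    raise ValueError(f"unknown selection {species!r}")


def profile_1d(traj: Trajectory, topo: Topology, species: str = "water",
               bin_width: float = 0.02) -> DensityProfile1D:
    """Mass-weighted z histogram averaged over frames and the xy plane."""
    sel = _selection_indices(topo, species)
    if len(sel) == 0:
        raise ValueError(f"selection {species!r} is empty")
    L = traj.box.lengths
    if bin_width > L[2]:
        raise ValueError("bin width exceeds the box extent")
    edges = np.arange(0.0, L[2] + bin_width, bin_width)
    masses = topo.masses[sel]
    acc = np.zeros(len(edges) - 1)
    for fr in traj:
        z = np.clip(fr.positions[sel, 2], 0.0, L[2] - 1e-9)
        acc += np.histogram(z, bins=edges, weights=masses)[0]
    area = L[0] * L[1]
    dens = acc / traj.n_frames / (area * bin_width) * AMU_PER_NM3_TO_G_CM3
    return DensityProfile1D(0.5 * (edges[:-1] + edges[1:]), dens, bin_width,
                            area, traj.n_frames)


def map_2d(traj: Trajectory, topo: Topology, species: str = "water",
           bin_width: float = 0.05, cap: float = 2.0) -> DensityMap2D:
    """y-averaged (x, z) mass-density grid."""
    sel = _selection_indices(topo, species)
    if len(sel) == 0:
        raise ValueError(f"selection {species!r} is empty")
    L = traj.box.lengths
    if bin_width > min(L[0], L[2]):
        raise ValueError("bin width exceeds the box extent")
    # bins tile the box exactly (no diluted partial bin on the periodic axis)
    nx = max(1, int(round(L[0] / bin_width)))
    nz = max(1, int(round(L[2] / bin_width)))
    xe = np.linspace(0.0, L[0], nx + 1)
    ze = np.linspace(0.0, L[2], nz + 1)
    masses = topo.masses[sel]
    acc = np.zeros((nx, nz))
    for fr in traj:
        x = np.clip(fr.positions[sel, 0] % L[0], 0.0, L[0] - 1e-9)
        z = np.clip(fr.positions[sel, 2], 0.0, L[2] - 1e-9)
        acc += np.histogram2d(x, z, bins=(xe, ze), weights=masses)[0]
    vol = (L[0] / nx) * (L[2] / nz) * L[1]
    dens = acc / traj.n_frames / vol * AMU_PER_NM3_TO_G_CM3
    return DensityMap2D(0.5 * (xe[:-1] + xe[1:]), 0.5 * (ze[:-1] + ze[1:]),
                        dens, L[0] / nx, L[2] / nz, L[1], traj.n_frames,
                        cap=cap)


def rolling_amplitude(profile: DensityProfile1D, period: float) -> np.ndarray:
    """Oscillation amplitude vs z by demodulation at the layer period.

    For rho = rho0 + A(z) cos(2 pi z / period + phi) with A varying slowly,
    2 |<(rho - mean) exp(2 pi i z / period)>| over a one-period window
    returns A at the window centre (exact for linear A)."""
    z, rho = profile.z, profile.density
    half = max(1, int(round(period / profile.bin_width / 2)))
    amp = np.zeros_like(rho)
    phase = np.exp(2j * np.pi * z / period)
    for i in range(len(z)):
        lo, hi = max(0, i - half), min(len(z), i + half + 1)
        w = rho[lo:hi] - rho[lo:hi].mean()
        amp[i] = 2.0 * abs(np.mean(w * phase[lo:hi]))
    return amp


def qll_thickness(profile: DensityProfile1D | None = None,
                  labels=None, traj: Trajectory | None = None,
                  topo: Topology | None = None,
                  period: float = 0.3685,
                  amp_hi: float = 0.5, amp_lo: float = 0.1,
                  density_tol: float = 0.03,
                  ref_layers: int = 5,
                  frac_hi: float = 0.85, frac_lo: float = 0.15,
                  bin_width: float = 0.05) -> QllEstimate:
    """QLL thickness from a density profile (or from phase labels).

    Profile route: bulk-ice amplitude A0 is the median rolling amplitude
    over the ``ref_layers`` layers nearest the seed bottom; crossings at
    ``amp_hi``*A0 and at ``amp_lo``*A0 (the latter also requiring mean
    density within ``density_tol`` of the bulk-liquid plateau) are
    linearly extrapolated to A0 and 0 to give z_ice and z_liq.

    Labels route: z_ice/z_liq are the ``frac_hi``/``frac_lo`` crossings of
    the time-averaged ice-fraction profile.
    """
    if profile is not None:
        return _qll_from_profile(profile, period, amp_hi, amp_lo,
                                 density_tol, ref_layers)
    if labels is None or traj is None or topo is None:
        raise ValueError("pass either a profile or (labels, traj, topo)")
    return _qll_from_labels(labels, traj, topo, frac_hi, frac_lo, bin_width)


def _qll_from_profile(profile, period, amp_hi, amp_lo, density_tol,
                      ref_layers):
    z, rho = profile.z, profile.density
    amp = rolling_amplitude(profile, period)
    occupied = rho > 1e-6
    if not occupied.any():
        raise ValueError("empty density profile")
    z_lo_data = z[occupied][0]
    ref = (z >= z_lo_data) & (z <= z_lo_data + ref_layers * period)
    a0 = float(np.median(amp[ref]))
    if a0 <= 0:
        raise ValueError("no crystalline oscillation near the seed bottom")
    # bulk liquid plateau: low amplitude region above the ice
    calm = occupied & (amp <= amp_lo * a0)
    above = calm & (z > z_lo_data + ref_layers * period)
    if not above.any():
        if np.all(amp[occupied] >= amp_hi * a0):
            return QllEstimate(z_ice=float(z[occupied][-1]),
                               z_liq=float(z[occupied][-1]))  # fully ordered
        raise ValueError("no bulk-liquid plateau found above the ice")
    rho_liq = float(np.mean(rho[above]))
    # crossings, scanning upward
    hi_ok = amp >= amp_hi * a0
    idx_hi = np.where(hi_ok & occupied)[0]
    z50 = z[idx_hi[-1]]
    a50 = amp[idx_hi[-1]]
    after = np.where((z > z50) & occupied & (amp <= amp_lo * a0) &
                     (np.abs(rho - rho_liq) <= density_tol * rho_liq))[0]
    if len(after) == 0:
        raise ValueError("no qualifying liquid boundary above the ice")
    z10, a10 = z[after[0]], amp[after[0]]
    if z10 <= z50 or a50 <= a10:
        return QllEstimate(z_ice=float(z50), z_liq=float(z50))
    # initial boundary guesses by linear extrapolation of the crossings
    slope0 = (a10 - a50) / (z10 - z50)
    zi0 = z50 + (a0 - a50) / slope0
    zl0 = z50 - a50 / slope0
    # refine by fitting a decay ramp convolved with the demodulation
    # window (the rolling window rounds the ramp corners; fitting the
    # rounded model keeps narrow transitions unbiased)
    lo = max(z[0], zi0 - 2 * period)
    hi = min(z[-1], zl0 + 2 * period)
    mask = (z >= lo) & (z <= hi)
    if mask.sum() >= 8:
        def model(zz, zi, zl):
            return _smoothed_ramp(zz, zi, zl, a0, period)
        try:
            (zi, zl), _ = curve_fit(model, z[mask], amp[mask],
                                    p0=[zi0, zl0], maxfev=5000)
            if zl > zi:
                zi0, zl0 = zi, zl
        except RuntimeError:
            pass
    return QllEstimate(z_ice=float(zi0), z_liq=float(max(zl0, zi0)))


def _smoothed_ramp(z, zi, zl, a0, window):
    """Ramp a0 -> 0 over [zi, zl], box-smoothed over ``window``."""
    zi, zl = min(zi, zl), max(zi, zl)
    half = window / 2.0
    lo, hi = z - half, z + half

    # piecewise closed form of the running integral of the ramp
    def ramp_int(u):
        u = np.asarray(u, dtype=float)
        out = np.where(u <= zi, a0 * u, 0.0)
        mid = (u > zi) & (u < zl)
        w = zl - zi if zl > zi else 1e-12
        um = np.clip(u, zi, zl)
        out = np.where(mid, a0 * zi + a0 * ((um - zi) -
                                            (um - zi) ** 2 / (2 * w)), out)
        out = np.where(u >= zl, a0 * zi + a0 * w / 2.0, out)
        return out

    return (ramp_int(hi) - ramp_int(lo)) / window


def qll_series(labels, traj: Trajectory, topo: Topology,
               frac_hi: float = 0.85, frac_lo: float = 0.15,
               bin_width: float = 0.05) -> QllEstimate:
    """Per-frame QLL thickness from the ice-fraction profile.

    Returns the all-frame estimate with a ``per_frame`` table (time,
    z_ice, z_liq, thickness) attached; the mean and standard deviation
    of the per-frame thicknesses summarise the series.
    """
    rows = []
    for t in range(labels.n_frames):
        one = PhaseSlice(labels, t)
        sub = Trajectory([traj[t]], traj.box)
        try:
            est = _qll_from_labels(one, sub, topo, frac_hi, frac_lo,
                                   bin_width)
            rows.append((labels.times[t], est.z_ice, est.z_liq,
                         est.thickness))
        except ValueError:
            rows.append((labels.times[t], np.nan, np.nan, np.nan))
    per = pd.DataFrame(rows, columns=["time", "z_ice", "z_liq", "thickness"])
    overall = _qll_from_labels(labels, traj, topo, frac_hi, frac_lo,
                               bin_width)
    overall.per_frame = per
    return overall


class PhaseSlice:
    """Single-frame view of a PhaseLabels object."""

    def __init__(self, labels, t):
        self.ice = labels.ice[t:t + 1]
        self.times = labels.times[t:t + 1]
        self.n_frames = 1


def _qll_from_labels(labels, traj, topo, frac_hi, frac_lo, bin_width):
    o_idx = topo.water_oxygen_idx
    L = traj.box.lengths
    edges = np.arange(0.0, L[2] + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    num = np.zeros(len(centers))
    den = np.zeros(len(centers))
    for t, fr in enumerate(traj):
        which = np.clip(np.digitize(fr.positions[o_idx, 2], edges) - 1,
                        0, len(centers) - 1)
        for b in range(len(centers)):
            sel = which == b
            den[b] += sel.sum()
            num[b] += labels.ice[t, sel].sum()
    frac = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    occ = den > 0
    hi_idx = np.where(occ & (frac >= frac_hi))[0]
    if len(hi_idx) == 0:
        raise ValueError("no crystalline region in the ice-fraction profile")
    z_ice = centers[hi_idx[-1]]
    lo_idx = np.where(occ & (frac <= frac_lo) & (centers > z_ice))[0]
    if len(lo_idx) == 0:
        return QllEstimate(z_ice=float(z_ice), z_liq=float(z_ice))
    return QllEstimate(z_ice=float(z_ice), z_liq=float(centers[lo_idx[0]]))
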