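"""Experimental-side calculators: branching degree, growth rate, grain
sizes, NMR relaxation and diffusion fits.

These are the bench-side counterparts of the simulation analyses: the
degree of branching DB = 2D/(2D + L13 + L14) from inverse-gated 13C unit
integrals, the one-directional ice-growth rate, the mean largest grain
size (MLGS) from splat-assay recrystallization, the biexponential CPMG
T2 fit with Bloembergen-Purcell-Pound (BPP) inversion to a rotational
correlation time, and the Stejskal-Tanner fit of pulsed-field-gradient
(DOSY) decays to a translational diffusion coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

BPP_C_WATER = 5.33e9   # s^-2, dipolar constant for water protons
GAMMA_1H = 2.675221874e8   # rad s^-1 T^-1


@dataclass(frozen=True)
class PolymerComposition:
    """Unit integrals from inverse-gated 13C NMR (any consistent units)."""

    D: float
    L13: float
    L14: float
    T: float = 0.0

    def __post_init__(self):
        if min(self.D, self.L13, self.L14, self.T) < 0:
            raise ValueError("unit integrals must be non-negative")


@dataclass(frozen=True)
class FrontObservation:
    """One-directional freezing observation (micrometres, seconds)."""

    d_half: float        # distance from start to the centreline, um
    elapsed: float       # time to travel it, s
    d_0: float = 0.0     # starting front position, um

    def __post_init__(self):
        if self.elapsed <= 0:
            raise ValueError("elapsed time must be positive")
        if self.d_half < 0:
            raise ValueError("distance must be non-negative")


@dataclass
class RelaxationFit:
    """Biexponential T2 fit, components ordered T_2a <= T_2b."""

    f_2a: float
    T_2a: float      # ms
    f_2b: float
    T_2b: float      # ms
    E_0: float
    residual: float


@dataclass
class DosyFit:
    """Stejskal-Tanner regression result."""

    D: float         # m^2/s
    S_0: float
    r_squared: float


def degree_of_branching(comp: PolymerComposition) -> float:
    """DB = 2D / (2D + L13 + L14), in [0, 1].

    Scale-invariant in the integrals; T units do not enter.
    """
    denom = 2.0 * comp.D + comp.L13 + comp.L14
    if denom <= 0:
        raise ValueError("2D + L13 + L14 must be positive")
    return 2.0 * comp.D / denom


def growth_rate(obs: FrontObservation) -> float:
    """Ice-front velocity in um/s: distance to centre over time to centre."""
    return obs.d_half / obs.elapsed


def mlgs(grain_sizes, reference_mlgs: float,
         allow_fewer: bool = False) -> tuple[float, float]:
    """Mean largest grain size and recrystallization index.

    MLGS is the mean of the 10 largest grains (strict protocol: fewer
    than 10 grains is an error unless ``allow_fewer``); RI is MLGS as a
    percentage of the pure-water reference.
    """
    sizes = np.asarray(sorted(grain_sizes, reverse=True), dtype=float)
    if len(sizes) < 10 and not allow_fewer:
        raise ValueError(f"need >= 10 grains, got {len(sizes)}")
    if len(sizes) == 0:
        raise ValueError("no grains")
    if reference_mlgs <= 0:
        raise ValueError("reference MLGS must be positive")
    m = float(np.mean(sizes[:10]))
    return m, 100.0 * m / reference_mlgs


def _biexp(t, f_a, t2_a, f_b, t2_b, e0):
    return f_a * np.exp(-t / t2_a) + f_b * np.exp(-t / t2_b) + e0


def t2_biexp_fit(t, e_t) -> RelaxationFit:
    """Nonlinear least squares of E_t = f_a exp(-t/T2a) + f_b exp(-t/T2b) + E0.

    Initialised from a log-linear fit of the tail (slow component) and of
    the early residual (fast component); components are order-normalised
    so T_2a <= T_2b and amplitudes are bounded non-negative.
    """
    t = np.asarray(t, dtype=float)
    e = np.asarray(e_t, dtype=float)
    if len(t) < 6:
        raise ValueError("need at least 6 samples")
    e0_guess = max(float(e.min()), 0.0)
    pos = e - e0_guess > 1e-12
    tail = t > np.median(t)
    use = pos & tail
    if use.sum() >= 2:
        slope, intercept = np.polyfit(t[use], np.log(e[use] - e0_guess + 1e-12), 1)
        t2_slow = -1.0 / slope if slope < 0 else float(t.max())
        f_slow = float(np.exp(intercept))
    else:
        t2_slow, f_slow = float(t.max()) / 2, float(e[0]) / 2
    resid = e - f_slow * np.exp(-t / max(t2_slow, 1e-9)) - e0_guess
    early = (t <= np.median(t)) & (resid > 1e-12)
    if early.sum() >= 2:
        slope, intercept = np.polyfit(t[early], np.log(resid[early]), 1)
        t2_fast = -1.0 / slope if slope < 0 else t2_slow / 4
        f_fast = float(np.exp(intercept))
    else:
        t2_fast, f_fast = max(t2_slow, 1e-6) / 8, max(float(e[0]) - f_slow, 1e-3)
    p0 = [max(f_fast, 1e-9), max(t2_fast, 1e-9),
          max(f_slow, 1e-9), max(t2_slow, 1e-9), e0_guess]
    try:
        popt, _ = optimize.curve_fit(
            _biexp, t, e, p0=p0,
            bounds=([0, 1e-9, 0, 1e-9, -np.inf], np.inf), maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"T2 fit did not converge: {err}") from err
    f_a, t2_a, f_b, t2_b, e0 = popt
    if t2_a > t2_b:
        f_a, t2_a, f_b, t2_b = f_b, t2_b, f_a, t2_a
    residual = float(np.sqrt(np.mean((_biexp(t, f_a, t2_a, f_b, t2_b, e0)
                                      - e) ** 2)))
    return RelaxationFit(float(f_a), float(t2_a), float(f_b), float(t2_b),
                         float(e0), residual)


def bpp_rate(tau_c: float, omega0: float, C: float = BPP_C_WATER) -> float:
    """Forward BPP map: 1/T2 as a function of the correlation time (s)."""
    w2t2 = (omega0 * tau_c) ** 2
    return (C / 2.0) * (3.0 * tau_c + 5.0 * tau_c / (1.0 + w2t2)
                        + 5.0 * tau_c / (1.0 + 4.0 * w2t2))


def bpp_tau_c(T2: float, omega0: float, C: float = BPP_C_WATER,
              bracket: tuple[float, float] = (1e-13, 1e-6)) -> float:
    """Invert the BPP equation for the rotational correlation time.

    The forward map is strictly monotone in tau_c over the bracket, so
    bisection on log tau_c finds the unique root.
    """
    if T2 <= 0:
        raise ValueError("T2 must be positive")
    target = 1.0 / T2

    def f(log_tau):
        return bpp_rate(10.0 ** log_tau, omega0, C) - target

    lo, hi = np.log10(bracket[0]), np.log10(bracket[1])
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("no BPP root inside the bracket; T2 out of range")
    root = optimize.brentq(f, lo, hi, xtol=1e-12)
    return float(10.0 ** root)


def dosy_fit(G, S, gamma: float = GAMMA_1H, delta: float = 2e-3,
             Delta: float = 20e-3) -> DosyFit:
    """Stejskal-Tanner fit: ln S = ln S0 - D * gamma^2 G^2 delta^2 (Delta - delta/3).

    Linear regression of ln(S) on the gradient factor; the slope is the
    translational diffusion coefficient in m^2/s.
    """
    G = np.asarray(G, dtype=float)
    S = np.asarray(S, dtype=float)
    if len(G) < 3:
        raise ValueError("need at least 3 gradient amplitudes")
    if np.any(S <= 0):
        raise ValueError("signal amplitudes must be positive")
    x = gamma ** 2 * G ** 2 * delta ** 2 * (Delta - delta / 3.0)
    res = stats.linregress(x, np.log(S))
    return DosyFit(D=float(-res.slope), S_0=float(np.exp(res.intercept)),
                   r_squared=float(res.rvalue ** 2))
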