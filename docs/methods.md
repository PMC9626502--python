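# Methods

This note documents the models and estimators implemented in
`icegrowth`, the defaults they ship with and why, what the synthetic
generators do and do not emulate, and the numerical choices made where
the design was genuinely open. Units are nm, ps, amu and g/cm³ unless
stated otherwise.

## Ice/liquid classification

Waters are classified per frame from oxygen geometry alone. For oxygen
*i* with neighbours *j* within `r_cut` (default 0.35 nm, the first
O–O coordination shell), the degree-6 bond-orientational vector is

    q6m(i) = (1/N_b) Σ_j Y6m(r_ij),   m = −6 … 6,

normalised to unit length. Neighbours *i*, *j* are *connected* when
Re⟨q6(i)·q6*(j)⟩ > `q_threshold` (default 0.7), and a water is ICE when
it has at least `min_connections` (default 3) connected neighbours.
This is the standard ten Wolde–Frenkel construction for
crystallinity in water; with these defaults an ideal ice Ih lattice is
100% ICE (the most weakly coordinated surface oxygens have exactly 3
connections) and a 0.24 nm-minimum-separation random liquid shows
≤ 0.5% ICE, so the two phases are cleanly separable. All three
parameters are exposed. Neighbour search uses a periodic KD-tree; an
independent O(N²) loop implementation in the test suite must agree
*exactly*, label by label.

A caveat that matters for interpretation: a crystalline layer directly
in contact with disordered liquid loses part of its connections to the
liquid contamination of its q6 vectors. Buried layers classify at 100%;
the topmost grown layer classifies at 50–70% until it is covered. This
mirrors physical interface premelting and is why layer selection for
back-tracking targets buried layers.

## Front height and step detection

h(t) is the top of the ice body that is vertically connected to the
seed slab. Waters are binned along z (default 0.05 nm); a bin qualifies
when it holds ≥ `min_count` (3) waters with ice fraction ≥ `occupancy`
(0.5); qualifying bins are chained bottom-up tolerating gaps up to
`gap_tol` (0.45 nm — an ice bilayer has ~0.18 nm of empty space inside
it and ~0.28 nm between bilayers, both below the tolerance, while a
detached cluster floating in the liquid is further away and is
excluded). h is the mean oxygen z inside the highest chained bin rather
than the bin centre: the bin grid would quantise h to ±half a bin
(0.025 nm), which is the same order as the 0.02 nm tolerance on the
step-height target, whereas the mean-z of the top sublayer is exact for
lattice-frozen layers. The `min_count` floor exists because one or two
stray templated waters above the front can form a spuriously "icy" bin
with 50% occupancy out of two molecules.

Steps are extracted by recursive binary segmentation of h(t): each
segment is split at the point minimising the summed squared error, the
split is kept when the plateau means differ by ≥ `min_rise` (0.1 nm),
and sub-threshold changes are merged into their neighbours. A step is
reported as (midpoint time between the bracketing frames, rise between
plateau means). On a staircase with rises of 0.37 nm and noise
σ = 0.02 nm the detector recovers every step at ± one frame.

## Density fields and QLL thickness

Density profiles are mass-weighted histograms divided by bin volume,
averaged over frames; bins tile the box exactly so no partial bin is
diluted on a periodic axis, and Σρ·V equals the selected mass to 0.1%
at every binning.

The QLL estimator works on the z-profile of water density. Crystalline
ice oscillates at the layer period (basal c/2 = 0.3685 nm); bulk liquid
is flat. The local oscillation amplitude A(z) is measured by
demodulation: over a rolling one-period window,
A(z) ≈ 2|⟨(ρ−ρ̄)·e^{2πiz/period}⟩|, which returns the envelope exactly
for a linearly varying amplitude. The bulk-ice reference A0 is the
median amplitude over the 5 layers nearest the seed bottom (a stable
zone away from the interface). Boundary crossings are located where
A(z) falls to 50% of A0 and, above that, to 10% of A0 with mean density
within 3% of the bulk-liquid plateau — crossing levels chosen away from
the noisy extremes. Because the window convolution rounds the ends of
the decay, the two crossings are then used only to initialise a
least-squares fit of a *box-smoothed linear ramp* (the analytic
convolution of a linear A0→0 decay with the demodulation window) whose
two parameters are the boundaries z_ice and z_liq; thickness =
z_liq − z_ice. This model-based step is what makes the estimator
unbiased for narrow transitions: on constructed profiles with
transition widths 0.5–3 nm it recovers the width to ≤ 0.015 nm, is
monotone in the true width, and is invariant to bin size up to one bin
for bins ≤ 0.05 nm. A profile whose amplitude never decays below 50%
of A0 is fully ordered (thickness 0); one whose amplitude decays but
that has no liquid plateau is an error. When phase labels are supplied
instead of a profile, z_ice/z_liq are the 85%/15% crossings of the
time-averaged ice-fraction profile — a coarser, more robust route for
short noisy desk-scale trajectories. All thresholds are exposed; the
choice of 50%/10%, ±3% and 85%/15% is an operational definition, since
the QLL has no unique microscopic boundary.

At publication scale (hundreds of ns of all-atom MD) this estimator is
the operational definition of QLL thicknesses near 1.1–1.9 nm; at desk
scale only constructed-profile recovery is asserted, because a static
synthetic liquid has no thermally averaged interfacial profile.

## Hydrogen bonds

Geometric criterion: donor···acceptor heavy-atom distance ≤ `d_max`
(0.35 nm) and donor–H···acceptor angle at the hydrogen ≥ `angle_min`
(150°), under PBC, both donation directions counted, intramolecular
pairs excluded. These are the dominant convention for water and are
exposed.

Lifetimes use continuous survival: a bond's run is the maximal stretch
of frames in which it is present, tolerating interruptions up to
`allow_gap` frames (default 1, guarding against frame-stride flicker).
S(t) is the fraction of bond-formation events still intact after lag t,
and the scalar lifetime is the step-function integral dt·ΣS(k), which
equals the mean bonded duration: a bond lasting exactly 10 frames of
10 ps has lifetime 100 ps, and telegraph bonds with exponential
breaking rate k are recovered within a few percent of 1/k. Survival is
averaged over formation events rather than over every occupied frame:
frame-origin averaging would halve the lifetime of a deterministic bond
(mean residual life T/2) while leaving the exponential case unchanged,
and the scalar "lifetime" reported alongside bond counts is meant to be
the mean bonded duration.

Multiplicity is counted per (water molecule, polymer molecule) pair per
frame — the number of simultaneous distinct bonds, pooling donor and
acceptor roles — histogrammed as 1/2/3/4+ with the multiple fraction
Σ_{m≥2}. Tightening `d_max` can only remove bonds, so the multiple
fraction is non-increasing, which is asserted as a property test.

## Iso-configurational mobility

The propensity of water *i* is DP_i = (1/M) Σ_m |r_i^{(m)}(t*) −
r_i(0)|², over M runs sharing the initial configuration (verified to
10⁻⁶ nm) with PBC-unwrapped displacements. Defaults t* = 100 ps and
M = 20 are exposed; the desk-scale tests use shorter t* since for
Brownian dynamics the DP contrast between populations is scale-free.
MI and MM are the bottom/top round(0.05·N) molecules with a stable
(DP, id) tie-break so the sets are deterministic.

Shell diffusion assigns each water to the innermost shell (default
outer radii 0.5/1.0/2.0 nm) covering its minimum O-to-polymer-heavy-atom
distance at each time origin, requires residence in that shell for the
whole fit window by default, and takes D as the slope/6 of a linear MSD
fit over the window (default 10–50 ps). The residence rule keeps slow
and fast populations from mixing mid-window, at the price of slightly
censoring the largest excursions of molecules that start near a shell
boundary — a ~2–4% downward bias at the defaults, which the exposed
`residence` switch removes when the mobility field is known to be
time-invariant (as in the synthetic recovery tests). Recovery of
generator coefficients is within 5% per shell at the test's problem
size (400 molecules per shell band, 10 independent runs, 2–10 ps fit
window).

The polymer's lateral path is the unwrapped mass-weighted COM (x, y)
series; a frame is DWELL when the rolling RMS displacement about the
window-mean position is below `dwell_rms` (default 0.1 nm) over
`dwell_window` (default 100 ps), else MIGRATE; runs of equal labels
become segments.

## Back-tracking

A frozen layer is selected at the final analysed frame either by
lattice layer index (z bounds from the generating lattice) or by an
explicit z window; every water inside must be ICE-labelled, otherwise
the layer is not fully frozen and selection fails. The trajectory is
then walked backwards over a window (default 20 ns) at a frame stride
(default such that 10 ps spacing yields 2000 frames), recording every
water–polymer H-bond of the selected waters. Per water: `via_pg` is
true iff at least one contact frame exists; the attributed segment is
the one with the most contact frames, ties broken by the most recent
contact (each frozen water is assigned exactly one unit colour, and the
contact closest to freezing is the most mechanistically relevant tie
winner); multiplicity is the maximum simultaneous bond count with any
one polymer molecule. Layer summaries report the via-polymer fraction,
segment fractions among via-polymer waters (summing to 1), and the
multiplicity distribution.

On scripted trajectories the whole chain — selection, classification,
attribution, multiplicity — reproduces the generator's log with zero
errors, and is stride-independent whenever the stride divides the
scripted contact times.

## Synthetic systems: what they emulate, and what they do not

The generators produce the geometric and kinematic skeleton of an
ice-growth simulation with every analysable fact known:

- **Ice slab** — proton-naive ideal ice Ih: oxygens on the hexagonal
  lattice (a = 0.452, c = 0.737 nm; 0.917 g/cm³; O–O 0.276 nm; basal
  bilayers every c/2 = 0.3685 nm), two hydrogens per oxygen placed
  along O–O bond directions without Bernal–Fowler bookkeeping. Every
  analysis here depends on oxygen geometry and local H-bond geometry,
  not proton order. Prism orientations are built by permuting axes so
  the requested face normal lies along z.
- **Polymer** — a bead-per-unit tree grown by random attachment with a
  scheduled number of degree-3 branch nodes so the realised degree of
  branching matches the target within 1/(n−2); unit types from graph
  degree (leaf→T, degree-2→L13/L14 split by a declared ratio,
  branch→D); coordinates by a self-avoiding walk; one hydroxyl
  (O donor/acceptor + H) per unit. A strictly linear chain has DB = 0
  exactly; DB recomputed from the generated unit counts equals the
  generator's own value by construction.
- **Mixed system** — liquid placed by rejection sampling at
  33.4 molecules/nm³ (≈ 1.00 g/cm³) with 0.24 nm minimum separation
  between placement sites (heavy atoms; the hydrogens riding 0.1 nm
  from their oxygen are not separation-constrained), starting 0.15 nm
  above the slab (the same clearance the growth scripting maintains, so
  the seed's top layer stays crystalline for the classifier); polymers
  inserted with COM 2 nm above the seed.
- **Scripted growth** — at each step time one whole liquid layer snaps
  onto the next lattice bilayer (waters chosen by a minimum-cost
  assignment of the lowest liquid molecules to the sites); displaced
  bystander liquid is lifted above the new front, with the liquid
  ceiling rising so the remaining water never exceeds bulk density.
  Scripted H-bond events are realised geometrically — the named
  hydroxyl placed 0.28 nm from the named water with its H collinear,
  the water's own hydrogens pointed away, bystanders pushed outside
  detection range — so the emitted log is the exact set of
  polymer–water bonds present (guaranteed when the polymer is parked,
  i.e. no explicit COM path is scripted). The polymer is otherwise
  parked on a grid in the headroom above the liquid ceiling.
- **ISOCA ensembles** — overdamped Gaussian random walks per molecule
  with per-axis step variance 2DΔt, frozen sets immobile, run seeds
  derived from (seed, run index).

Not emulated: forces, thermostats/barostats, water-model specifics
(4-site virtual sites are parsed and carried but reduced to O + 2H for
analysis), proton-disorder sampling, premelting dynamics, and any real
kinetics of attachment. Consequently a passing test demonstrates that
the *estimators* are correct and unbiased on systems whose ground truth
is known — not that the MD observables of a real interface take any
particular value. The headline MD numbers (QLL thicknesses of
11–19 Å, H-bond lifetimes of ~100–150 ps, multiple-bond proportions,
shell diffusion coefficients, back-tracking percentages) require
hundreds of ns of all-atom simulation and are the quantities these
pipelines *define*, not desk-scale reproducibles.

## Wet-lab formulas

- DB = 2D/(2D + L13 + L14); scale-invariant; terminal units do not
  enter. With the published rounded unit percentages (D 32, L13 12,
  L14 24) the formula gives 0.64 — the calculator computes from its
  inputs and performs no reconciliation with values derived from
  unrounded integrals.
- Growth rate V = d_½ / t(d_½ − d_0) in μm/s.
- MLGS = mean of the 10 largest grains (strict: fewer than 10 grains is
  an error; a permissive flag averages all), RI = 100·MLGS/reference.
- T2: nonlinear least squares of f_a·e^{−t/T2a} + f_b·e^{−t/T2b} + E0
  with non-negative amplitudes, initialised from a log-linear fit of
  the tail and of the early residual, components order-normalised
  T2a ≤ T2b. Noise-free recovery is within 1%; under 1% additive noise
  individual fits of the fast component scatter by up to ~10% (an
  intrinsic identifiability limit of biexponentials, not a code
  property), so the seeded-repeat tests assert that the *mean* over 100
  repeats is unbiased within 5%.
- BPP: 1/T2 = (C/2)(3τc + 5τc/(1+ω₀²τc²) + 5τc/(1+4ω₀²τc²)) with
  C = 5.33×10⁹ s⁻²; the forward map is strictly monotone on
  τc ∈ [10⁻¹³, 10⁻⁶] s (asserted numerically), so bracketed root
  finding on log τc returns the unique inverse; round trips agree to
  10⁻⁴ relative.
- DOSY: linear regression of ln S on γ²G²δ²(Δ − δ/3); D = −slope. The
  standard Stejskal–Tanner form with δ² and a negative exponent is
  implemented. With the experimental gradient schedule
  (0.021–0.52 T/m, δ = 2 ms, Δ = 20 ms) a D of 10⁻¹⁰ m²/s attenuates
  the signal by only ~15%, so 2% multiplicative noise propagates to
  ~10% scatter on single fits; as with T2, the repeat tests assert mean
  unbiasedness within 5%.

## Problem sizes and determinism

The shipped tests and the acceptance script run on deliberately small
systems — a 3×2-cell, 3-layer seed slab (72 waters) under ~180 liquid
waters, 60 frames at 10 ps; 400 molecules per shell × 10 runs for
diffusion recovery; 1000 molecules × 20 runs for MI purity; 100 random
150-water frames for the brute-force equivalence — sizes chosen so the
statistical tolerances stated above hold with margin. Every stochastic
stage takes an explicit seed and is reproducible bit-for-bit, including
byte-identical trajectory files for identical inputs.

## Known limitations

- The q6 classifier does not distinguish cubic from hexagonal stacking,
  and the exposed growth front classifies as partially liquid (see
  above); analyses that need a fully frozen layer must use buried ones.
- Scripted-growth ground-truth exactness for H-bond events is
  guaranteed only while the polymer is parked; when a lateral COM path
  is scripted, incidental contacts along the path are physical but
  unlogged.
- `front_height` assumes z is the freezing axis; inputs must be rotated
  upstream.
- The GRO/XYZ writers are fixed-precision (10⁻³ nm and 10⁻⁶ nm); round
  trips are exact only to format precision.
- Temperature is metadata only (recorded as 268 K); no analysis uses it.
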