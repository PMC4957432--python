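# Methods

This note records the model the code implements, the choices behind the
defaults, the numerical scheme, and its known limitations.  Units and
symbols follow the source modules (`nefire.kernel`, `nefire.simulator`).

## 1. Model

### 1.1 Geometry

The nuclear envelope is idealised as two concentric spherical surfaces of
common radius `R = 8 um` (the envelope gap of ~10 nm is negligible against
`R`).  Channels, pores and probes are points on that sphere; distances are
great-circle arc lengths.  Layouts are generated by a golden-section
spiral (deterministic, near-even), by seeded area-uniform sampling
(`phi` uniform, `cos(theta)` uniform), or as evenly spaced queues along a
great-circle arc.

### 1.2 Fields: lazy kernel superposition

Calcium on each surface diffuses freely in two dimensions while membrane
pumps remove it at a linear rate, so each point release of amount `sigma`
contributes

    c(dr, tau) = sigma * exp(-dr^2/(4 D tau) - k_s * tau) / (4 pi D tau)

and the surface concentration anywhere is the sum over past releases.
Nothing is integrated on a grid: concentration is *evaluated on demand* at
the points that matter (channels, pores, probes), which is exact for
linear dynamics.  The planar free-space kernel is used with the
great-circle metric; no wrap-around image terms are added.  This is a
deliberate approximation for the saltatory regime: with `k_s = 1/s` a
release decays by `e^-15 ~ 3e-7` before diffusion could make the field
wrap the `pi R ~ 25 um` half-circumference matter (`t >~ (pi R)^2 / 4D`
is 8–30 s for `D` = 20–5 um^2/s).

**Units.** Concentrations are `uM*`: molar over an implicit 1-um-deep
layer, so an amount in mol converts to `uM*.um^2` by `1e21`
(1 um^3 = 1e-15 L).  The canonical constants are only mutually consistent
under this convention — with `sigma = 2e-20 mol = 20 uM*.um^2`, `D = 5`,
`k_s = 1`, `alpha = 0.15`, `c_th = 0.0425 uM*`, the refractory-period
equation below yields 2.8599 s, matching the canonical 2.86 s.

### 1.3 Firing rule (CICR) and refractory period

A channel fires when the local concentration reaches `c_th`, releasing
`sigma` instantaneously.  After firing it is refractory.  Two analyses
follow in closed form:

* **Propagation condition.**  The concentration a single release produces
  at distance `dr` peaks at `t* = (s-1)/(2 k_s)` with
  `s = sqrt(1 + k_s dr^2 / D)`; the peak value is
  `sigma k_s / (2 pi D (s-1)) * exp(-k_s dr^2/(2D(s-1)) - (s-1)/2)`.
  A neighbour can be triggered iff that peak reaches `c_th`.  The code
  carries both this closed form and a bracketed numeric maximisation
  (pumps only pull the maximiser earlier, so `[0, dr^2/4D]` brackets it);
  the test suite holds them to 1e-7 relative agreement on a `(D, k_s)`
  grid.  With the canonical parameters the resulting trigger ranges are
  4.83 um (`D = 5`) and 6.09 um (`D = 20`).
* **Refractory period.**  A channel re-arms once its own released calcium
  (evaluated at its own position, `sigma exp(-k_s t) / (4 pi D t)`) decays
  below `alpha * c_th`.  That expression is strictly decreasing, so the
  crossing is unique; it is found by bracketed root-finding (`brentq`,
  upper bracket `sigma / (4 pi D alpha c_th)`, the exact pump-free root).
  `tau_R` = 2.8599 s on the `D = 5` surface and 1.8885 s on the `D = 20`
  surface.  The default "compartment" mode assigns each channel this
  per-compartment constant; a "local" mode that re-arms on the actual
  downward crossing of `alpha * c_th` at the channel is also implemented.

### 1.4 Pore coupling

Nuclear pores are passive Fick's-law couplers across the envelope
thickness `Dm = 0.01 um` with in-pore diffusion constant `D_P = 20 um^2/s`
and diameter `p_d = 0.029 um`.  Per step, each open pore transfers

    Omega = -(D_P / Dm) * (c_outer - c_inner) * pi (p_d/2)^2 * dt

applied as an exactly antisymmetric pair of point releases (`+Omega`
outer, `-Omega` inner), so pairwise conservation holds to floating-point
exactness — the recorded per-step totals of the two surfaces sum to zero.
The per-pore transfer coefficient is `g = (D_P/Dm) pi (p_d/2)^2
= 1.3210 um^3/s`.

## 2. Numerical scheme

### 2.1 Explicit stepping and causality

Time advances on a fixed grid `dt`.  Each step: (1) evaluate both
surfaces' concentrations at all pores, channels and probes using only
sources strictly older than the evaluation time (the kernel diverges at
age zero, and excluding same-step sources makes the scheme explicit and
order-independent); (2) emit the pore pulse pairs from the pre-step
gradient; (3) fire every enabled, non-refractory channel whose local
concentration reached `c_th`; (4) apply scheduled shut-offs.  Because
firing happens on the grid, measured inter-firing intervals quantise to
`dt` (e.g. 2.9 s at `dt = 0.1` for the 2.86 s refractory period).

### 2.2 Cost control (exact and approximate)

* Squared great-circle distances between all sources and all evaluation
  points are precomputed once.
* Inner loops skip any source/evaluation pair whose Gaussian or decay
  exponent exceeds 32 (`e^-32 ~ 1.3e-14`); this replaces a neighbour-list
  truncation radius with a branch-cheap exact bound.
* Channel releases older than `T_cut = -ln(epsilon)/k_s` (default
  `epsilon = 1e-6`, i.e. 13.8 s at `k_s = 1`) are dropped; the discarded
  field is below `epsilon` of its initial contribution.
* Pore pulses are emitted every step, which would make cost quadratic in
  step count, so the pulse history is coarsened in time: pulses younger
  than 0.4 s stay exact; older adjacent pulses are pairwise merged
  (amplitudes added, times amplitude-averaged) whenever the merged bin
  half-width is below 0.1 x its age.  The merge conserves amplitude
  exactly and is second-order accurate in the bin width.  The engine was
  validated against a brute-force implementation with no distance matrices
  and no history coarsening (12 pores, both sides, every step): maximum
  absolute probe difference 3.8e-19 uM*.

### 2.3 Recording

Channel-neighbourhood concentration is operationalised as the mean over a
ring of 3 probes at a 0.15 um offset around each channel (the canonical model
description fixes no radius); the global trace averages a 600-point
golden-spiral probe set.  Surface snapshots are evaluated on an
equal-area Mollweide grid.  Single-release experiments stop early once
the tracked probe has dropped to half its running maximum (recorded in
the manifest, so runs remain reproducible).

## 3. Experiment-level choices

### 3.1 Transmission saturation (Fig 2 replica)

The source-to-probe separation is not part of the canonical set (only
"distances larger than Ca2+ micro-domains" is required).  It is exposed as a parameter, with a documented
regime requirement: the half-the-release plateau only appears when the
probe's own kernel peak time `t*(separation)` is long compared with the
pore relaxation time `1/(2 g rho)` (~0.17 s at 2 pores/um^2) — i.e. the
separation must exceed about twice the equilibration length
`sqrt(4 D / (2 g rho))`, which is ~7.4 um at `D = 20`.  The default is
therefore 8 um.  The code demonstrates the failure mode at short range:
at 3 um and `D = 20` the envelope is still transparent — the maximum over
time of the *sum* of the two opposing probes equals the no-pore reference
to four digits — but the cross-side probe's own temporal peak passes
before equilibration and reads ~0.26 of the reference instead of 0.5.
With the 8 um default and equal `D = 20`, the sweep over even layouts
reaches 95% of its plateau at 2.0 pores/um^2 (0.5/um^2 grid), and the
plateau sits at 0.494 of the no-pore peak.  The saturation criterion
(plateau = mean of the top two grid values, which must agree within 2%;
report the smallest density reaching 95% of it) is grid-resolution
dependent by construction, which is why results carry their grid step.

### 3.2 Per-pore contributions (Fig 3 replica)

48 pores are queued along the C-to-P_N arc (spacing 4 pore diameters,
separation 6 um, `D_outer = 2`, `D_inner = 15`).  Each pore's recorded
pulse train is propagated to the probe with the inner-surface kernel and
accumulated up to the probe's peak time, then normalised by the total:
signed fractions that sum to 1 by construction.  Pores near the source
dominate (+0.34 for the nearest); pores near the probe are net negative
(calcium leaks back out where the inner surface is transiently richer).

### 3.3 Coupled oscillations (Fig 4 replica)

24 channels per side and 1500 pores (1.9 /um^2, within the transmission
plateau) are placed with seeded area-uniform sampling; `dt = 0.1 s`.
The outer surface (`D = 20`) sustains its own saltatory wave: trigger
range 6.09 um comfortably exceeds typical nearest-neighbour spacings at
24 channels per sphere.  The inner surface (`D = 5`, range 4.83 um)
cannot sustain a wave alone, but pore influx holds it above threshold, so
each inner channel fires as soon as it re-arms.  Measured medians (three
seeds): inner 2.9 s = `tau_R(D=5)` to within one `dt`; outer 1.9 s =
`tau_R(D=20)` likewise.  Swapping the side of the initial stimulus leaves
both medians unchanged.  Shutting off the outer side silences the inner
side after the residual trans-envelope calcium decays (a few seconds at
`k_s = 1`); shutting off the inner side leaves the outer rhythm unchanged.
Because placements are seeded rather than canonical, quantitative statements are
made on interval statistics across seeds, not on single trajectories.

## 4. Limitations

* The planar-kernel-with-arc-metric field is an approximation on the
  sphere; it is excellent in the pump-dominated saltatory regime but
  would be wrong for `k_s -> 0` or wrap-relevant time scales.
* Releases and pore pulses are instantaneous point events; channel open
  durations, stochastic gating and luminal store depletion are not
  modelled.
* Pore transfer uses the quasi-static Fick expression with the surface
  concentrations at the pore mouth; in-pore transport dynamics and
  electro-diffusion are ignored.
* The explicit scheme evaluates gradients one step back; pore fluxes are
  first-order accurate in `dt`, and firing times quantise to the grid.
* Figure pixels are not reproduction targets; only headline numbers
  and stated qualitative orderings are.  One canonical number is
  internally inconsistent: 2 pores/um^2 with `p_d = 0.029 um` covers
  ~0.13% of the surface, not the quoted 0.8%; the code reports computed
  coverage and does not force the quoted value.
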