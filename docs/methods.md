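# Methods

This note documents the models behind `oftmech`: what the synthetic phantom
emulates, how each analysis stage works, the numerical choices, and what
passing the test suite does and does not demonstrate about real data.

## The phantom

### Geometry and dynamics

The outflow tract is modelled as a straight tube of length L = 600 µm with
five analysis planes at equal spacing.  At axial position `z` and cardiac
phase `φ` (cycle fraction, period T = 0.37 s ≈ 2.5 Hz):

- **Radial activation.**  A raised-cosine pulse
  `w(φ) = cos²(π(φ − 0.5)/d)` on `|φ − 0.5| < d/2` (else 0) drives the inner
  myocardial radius `R(z,φ) = R_min(z) + ΔR(z)·w(φ − δ(z))`, with the
  peristaltic delay `δ(z) = z/(cT)` at wave speed c = 20 mm/s.  The open
  duty `d` is derived from the closure target: per-plane open windows are
  staggered by δ, so the fraction of the cycle with *every* plane closed is
  `1 − d − δ(L)`; setting that to 0.5 gives d ≈ 0.42.  Per-plane radii
  default to R_max = (0.21, 0.20, 0.19, 0.17, 0.15) mm and
  R_min = (0.14, 0.13, 0.12, 0.11, 0.12) mm, the proximal-to-distal taper
  and amplitude decline of the stage-18 tract.
- **Cardiac jelly and lumen.**  The jelly (extracellular matrix between
  myocardium and endocardium) closes the lumen at full contraction, so its
  cross-sectional area at closure is `πR_min²`; during expansion it shrinks
  by the factor `(1 − k_j·w)` (k_j = 0.4 by default), standing in for the
  longitudinal redistribution of the incompressible jelly as the tube
  stretches.  The lumen area is then `A = πR² − A_jelly`, which vanishes
  exactly on the closed plateau and opens smoothly.  The open lumen is an
  ellipse: the major semi-axis spans the inner circle up to a thin jelly
  margin (25 µm), the minor axis follows from the area, and near-circular
  states are clamped to a = b.  At full contraction the lumen degenerates to
  a slit along the major axis (the apposed cushion surfaces).  The lobe
  orientation rotates along the tube at 0.15°/µm (90° over the tract), the
  cushion spiral.
- **Myocardial wall.**  The outer radius conserves myocardial
  cross-sectional area during contraction.  Wall thickness at expansion
  defaults to (60, 52, 45, 38, 28) µm, thinning distally faster than the
  radius tapers — which is what makes the Laplace stress peak distally, an
  emergent ordering rather than a hard-coded one.
- **Pressures.**  Ventricular and aortic-sac pulses are raised-cosine
  pulses over a diastolic baseline, peaking at 196 Pa and 180 Pa at the
  phase of maximal proximal lumen area.  The ventricular pulse is wider
  (0.60 vs 0.45 cycle) so the driving difference is positive through the
  ejection window.  Traces are sampled at 100 Hz over 10 cycles and
  rescaled so the sampled maxima equal the configured peaks exactly.
- **Flow ground truth.**  The phantom's own flow field is the reduced-order
  solution (below) on the analytic geometry and generated pressures; the
  Doppler channel renders the corresponding elliptical Poiseuille profile.

### Imaging model

Each plane is rendered as 128×128 px at 5 µm pitch and 140 frames/s over
4 cycles (~208 frames).  Intensity levels: background 0.05, myocardium
0.85, jelly 0.18, lumen **and** endocardium 0.50 — the endocardium is
deliberately invisible against stagnant blood, as in the instrument.
Speckle is multiplicative gamma noise with contrast 0.25 (shape k = 1/0.25²);
depth attenuation is exponential along the beam (row) axis at 0.4 mm⁻¹.
Speckle statistics and the attenuation coefficient are free phantom
parameters, not claims about any instrument.  Each plane's movie starts at
an independent uniform-random cycle phase (acquisition is untriggered);
the start phases and the resulting activity lags are recorded in the ground
truth.  Doppler phase is `wrap(4π n τ V_z/λ₀)` plus Gaussian phase noise
(σ = 0.12 rad); pixels outside the lumen carry noise only.

What the phantom does **not** emulate: longitudinal wall motion (planes are
fixed in space; the ~20% longitudinal stretch enters only through the jelly
area modulation), tube curvature and the inner-curvature flow skew,
A-scan-level interferometric physics, red blood cells, and biological
variability.  Passing the recovery tests therefore shows the algorithms are
correct and robust to speckle, attenuation, phase noise and asynchronous
acquisition — not that they would meet the same error bounds on embryo
data.

## Reconstruction

The scalar *activity* signal (mean absolute frame-to-frame intensity
difference) is periodic at the heart rate and vanishes on the closed
plateau.  The period is the dominant autocorrelation peak (parabolic
refinement; among peaks within 5% of the maximum the smallest lag wins, so
multiples of the period are rejected).  Plane-to-plane lags come from
circular cross-correlation of period-folded activity signals on a 256-bin
phase grid.  The measured lag contains both the acquisition start offset
and the genuine peristaltic delay; these are not separable from per-plane
data alone, so `synchronize` accepts the modelled wave delays (known for
the phantom, configurable for real data) and adds them back, preserving the
proximal-to-distal closure ordering in canonical time.  Folding uses a
per-phase-bin median across cycles (phasor mean for the wrapped Doppler
channel) with circular interpolation of empty bins — the natural
generalization of cycle-wise averaging to a non-integer period.  The global
phase origin is the circular centre of the near-minimum plateau of the
proximal plane's central-patch intensity (the most-constricted state).

## Segmentation

Per frame, an attenuation-compensated image (log-linear fit to the row-wise
upper-decile intensity) is thresholded into layer masks: myocardial ring
(> 0.65), its filled interior, and the lumen window (0.34–0.67, the
midpoints between layer levels).  The interior is eroded by the smoothing
scale before the lumen mask is taken, because the smoothed jelly→myocardium
transition band aliases into the lumen intensity window.

Refinement is a classic parametric snake: cyclic pentadiagonal internal
energy (α = 0.1 elasticity, β = 0.05 stiffness), implicit-Euler update
`x ← (I + γA)⁻¹(x + γκF(x))`, convergence at < 0.1 px max displacement.
The external force is the gradient of the squared gradient magnitude of a
smoothed feature image, Gaussian-diffused to extend the capture range (a
cheap stand-in for gradient-vector-flow diffusion).  The feature image is
label-specific:

- myocardial boundaries use the intensity image with light smoothing and a
  short diffusion (σ = 1 px), so the two edges of a thin distal ring
  (≈ 5 px) do not merge and the weaker inner edge is not captured by the
  much stronger outer myocardium–background edge;
- the endocardium uses the smoothed *classified lumen mask* as a region
  force: its only gradient is the lumen boundary, so the snake is neither
  captured by the stronger jelly–myocardium edge across the thin cushion
  margin nor biased by speckle inside the lumen.

Closed-lumen frames return a flat, `degenerate`-flagged slit polygon along
the last open lumen's major axis (the true slit is invisible by
construction).  Temporal propagation warps the previous contour by a global
phase-correlation shift, refines, and falls back to from-scratch
segmentation when the snake area disagrees with the mask area by more than
20% (recovery from corrupted frames) or when the area jumps by more than
50% between frames.  Single-frame mask dropouts (a broken thin ring) keep
the propagated contour instead of collapsing to a slit.

Measured accuracy on default-noise phantoms: per-frame enclosed areas
within 5% of the cycle maximum for all three boundaries at all five planes;
endocardial Dice ≥ 0.97 at full expansion.

## Kinematics

Strain is contraction-positive and referenced to the largest perimeter:
`ε_θ(t) = (C_max − C(t))/C_max`.  This convention reproduces the
positive peak-contraction strains implied by the measured perimeter
extremes (e.g. C_max = 1.07 mm, C_min = 0.68 mm → 0.364).  The myocardium
is treated as circular through `R_eff = √(A_inner/π)`.  Derivatives are
centered differences on the periodic 196-phase grid — they annihilate
constants and are exact for linear series.  Closure is `A ≤ A_min +
0.05·(A_max − A_min)`; the 5% tolerance is a package choice (no standard
threshold exists for "closed"), and timing fractions sum to 1 by
construction.  Endocardial thickness at closure is offered under two
geometric models — slit (`t = 2A/C`) and annulus (`t = A/C`) — with the
model recorded in the output; neither is privileged because the closed
lumen's true geometry is not observable.

## Doppler velocimetry

`V_z = λ₀Δφ/(4πnτ)` gives ±11.996 mm/s at Δφ = ±π with the default
constants.  Temporal unwrapping (±2π corrections of successive differences)
doubles the unambiguous range; recovered axial velocities are clamped at
that doubled limit and samples near it are flagged as the wrap-plateau
artifact — beyond one unwrap the measurement saturates.  The centerline
series averages a small phasor window (5 samples) along the M-line to
suppress phase noise, unwraps each contiguous open stretch independently,
and reports closed-lumen frames as missing rather than zero.  Note that
unwrapping anchors each open stretch at its first sample; if the flow is
already beyond the single-pass limit there (as happens at moderate Doppler
angles when the filling wave arrives fast), the whole stretch lands on the
wrong 2π branch — the same failure mode that makes unwrapped instrument
data least reliable.  Angle correction divides by cos θ and amplifies noise
accordingly (×9.6 at θ = 84°).

## Wall stress

Thin-wall Laplace law `σ_θ = P·R/h` per plane, with `R` the effective inner
myocardial radius, `h` the cycle-averaged contour-derived wall thickness
(`R_out,eff − R_in,eff`), and `P` the linear blend `(1−s)·P_vent + s·P_as`
at the plane's normalized position.  Because pressures and wall motion come
from different sources, their relative phase is set by an explicit rule —
default: peak ventricular pressure at peak proximal lumen area — with the
shift recorded; the distal-exceeds-proximal peak-stress ordering is robust
to this choice.  Cardiac jelly is assumed load-free and no thick-wall
(Lamé) correction is applied.

## Hemodynamics

The lumen is a tapered elliptical duct with semi-axes `a(z,t) ≥ b(z,t)`
fitted per plane per phase (least-squares ellipse; degenerate slits get
`b = b_floor` and a closed flag) and interpolated along z with
shape-preserving piecewise cubics (no overshoot into negative axes).  At
the Reynolds numbers of the early embryonic circulation (order 1–10) each
instant is quasi-steady:

- mass conservation with moving walls, `∂A/∂t + ∂Q/∂z = 0`, fixes `Q(z,t)`
  up to the inlet value;
- when the lumen is open end to end, the measured pressure drop closes the
  problem through `ΔP = ∫ R_hyd·Q dz` with
  `R_hyd = 4µ(a² + b²)/(πa³b³)`;
- when a closure front is present, each open segment carries only the
  wall-motion flow anchored to `Q = 0` at the front: filling enters through
  the inlet while the distal end is still shut, and the closing wave ejects
  blood through the outlet — so the flow is continuous across the
  peristaltic cycle instead of switching on abruptly.

The simulated window defaults to the cycle arc over which any part of the
tract is open (auto-detected, bridging single-phase segmentation dropouts);
a fixed window such as 0.43 T–0.93 T of a 370 ms cycle in 200 steps
(Δt = 0.925 ms) can be set explicitly.  z-integrals use composite Simpson
on ≥ 50 subintervals; `∂A/∂t` uses centered differences on the phase grid.
`b_floor = 1 µm` regularizes closure — flow is zeroed rather than driven
through a near-singular resistance.  Limitations inherited from the
reduction: no fluid inertia (an optional first-order correction with
ρ = 1060 kg/m³ exists but is off by default and ρ is a package assumption),
no secondary flows or curvature skew, and centerline velocities spike
unphysically in the instants a station pinches shut (the quasi-steady
squeeze-jet); those instants fall below the imaging resolution and are
masked in all comparisons.

Wall shear stress uses the elliptical Poiseuille profile:
`τ(s) = 2µ|U₀|·√(cos²s/a² + sin²s/b²)` at wall point `(a·cos s, b·sin s)`,
maximal at the minor-axis ends — the cushion surfaces — so the (z, s) map
of τ shows a ridge that rotates with the cushion spiral; fitting the ridge
orientation along z recovers the generator's spiral rate to a few percent.
Verified numerics: rigid circular/elliptical ducts match the closed forms
to ≲ 10⁻⁶ relative; mass residual < 10⁻⁶ (4th-order check, 400 axial
nodes); halving Δz and Δt changes peak U₀ by ≪ 1%.

## Problem sizes and reproducibility

Default runs use 5 planes × 4 cycles × 128² px, a 196-phase canonical
cycle, 200 flow time steps and 101 axial nodes; the full pipeline completes
in about a minute on one CPU.  All randomness flows from a single seed
(start phases, speckle, phase noise), and fixed seeds give bit-identical
phantoms and pipeline outputs.  Every artifact written to disk carries the
seed and a hash of the full configuration.
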