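# Methods

## Model

A single spherical condensate of radius R sits at the centre of a closed
spherical domain of radius L (a Cartesian box in the 3D solver). Prior to
bleaching the system is at phase-separation equilibrium: the total volume
fraction of condensate material is

    φ_tot(r) = φ_out + (φ_in − φ_out) · (1 + tanh((R − r)/ℓ)) / 2,

with interface width ℓ and partition coefficient P = φ_in/φ_out.
Photobleaching splits the material into bleached and unbleached species
whose sum remains the stationary φ_tot; the unbleached concentration c_u
then obeys

    ∂t c_u = ∇·[ D(φ_tot) ( ∇c_u − c_u ∇φ_tot/φ_tot ) ],

with no-flux outer boundaries. Deep in either phase the drift term
vanishes and c_u diffuses with D_in = D(φ_in) or D_out = D(φ_out). A
full bleach is the initial condition c_u = φ_out·Θ(r−R), optionally plus a
small uniform unbleached offset inside (incomplete bleaching and the fast
uniform recovery are folded into this t = 0 offset; no kinetic model is
attempted for the latter, whose physical origin is unknown).

Normalized fluorescence intensity (background-subtracted, divided by the
prebleach profile) measures u = c_u/φ_tot, which runs from 0 to ≈ 1. All
lengths are µm, times s, intensities dimensionless. Interfacial resistance
is deliberately absent: the model is the minimal one that explains the
boundary dynamics.

### Diffusivity across the interface

Equilibrium thermodynamics fixes only the endpoints D_in and D_out; the
mobility inside the interface is unknown. The solver interpolates the
*resistivity*: 1/(Dφ) linear in the tanh weight (`kind="resistive"`,
the default), with D linear in φ_tot available as `kind="linear"`. The
resistive form is chosen because the excess interface resistance
∫[1/(Dφ) − step] dr vanishes by antisymmetry of the tanh weight, so the
diffuse-interface solution converges to the sharp-interface model at first
order in ℓ. The linear-in-φ form carries an O(ℓ) spurious interface
resistance that is clearly visible at large P (≈ 5% profile error at
ℓ = R/100, P = 150, versus ≈ 0.5% for the resistive form). A practical
corollary: the mobility transition penetrates a distance ≈ ℓ·ln(κ_in/κ_out)/2
into the droplet (κ = Dφ), so fits must mask a margin of ≳ 4ℓ inside R
when ℓ is not small — the same reasoning behind the ten-pixel exclusion
used on experimental images, where the optically broadened interface plays
the role of ℓ.

## Solvers

**Radial (1D).** Cell-centred finite volumes with r²-weighted two-point
face fluxes. All three model levels evolve u = c_u/φ_tot, for which the
flux is −D φ_tot ∂r u: this makes the equilibrium profile an exact discrete
fixed point, conserves mass to round-off (the operator is symmetric with
zero column sums), and turns the sharp-interface jump condition
c(R⁻) = P·c(R⁺) into plain continuity of u with a harmonic face conductance
at the interface face — flux continuity and the jump hold by construction.
Grids are uniform with local refinement (≥ 4 cells per ℓ, default ℓ/4
spacing within 4ℓ of R); the sharp solver uses two uniform sub-grids
meeting at a face exactly at R. Time stepping is Crank–Nicolson with fixed
substeps per output interval (default ≈ 400 over the run) and four
backward-Euler start-up quarter-steps to damp the post-bleach corner
singularity (Rannacher smoothing); each step is one tridiagonal banded
solve. Against the closed-form eigenfunction series for constant-boundary
recovery in a sphere the solver is accurate to < 10⁻⁴ sup-norm at the
default resolutions.

**Cartesian (3D).** Same u-variable finite volumes on a uniform box grid
(spacing ≤ R/8 enforced), harmonic face conductances, Crank–Nicolson with
a Jacobi-preconditioned conjugate-gradient solve per step (the system is
symmetric positive definite by construction). Mass is conserved to the CG
tolerance (10⁻¹⁰ relative by default). φ_tot is the superposition of tanh
spheres clipped at φ_in; every outer box face is no-flux, so a coverslip
is simply a droplet placed at height h ≥ R above the z = 0 face. The 3D
runs are a deliberately coarse proxy — ℓ = R/10 at spacing R/8 — used for
directional and bound claims, not for pointwise curves; against the radial
solver on an equal-volume domain the droplet-averaged recovery agrees
within ≈ 1–3%.

**Boundary trace interpolation.** The measured trace c_u(R⁻, t) enters the
Dirichlet solver between frames via a shape-preserving monotone cubic
(PCHIP). The piecewise-linear alternative is kept as an option but biases
fitted D_in by several percent at realistic frame rates: the early trace is
strongly convex, and the secant systematically under-represents it. For the
same reason fitting starts after a short time lag (default: prebleach frame
plus two post-bleach frames dropped); the first retained frame, offset
included, is the initial condition.

## Image pipeline

Azimuthal averages use half-open 1-pixel bins by centre distance, pixel
centres at integer coordinates; an `effective_radii` option replaces
nominal bin centres by the mean actual pixel distance (it matters only when
a bin holds a handful of pixels, e.g. when profiling coarse simulation
grids). Camera background is subtracted uniformly; dividing by the
background-subtracted prebleach profile normalizes the recovery and cancels
static radial gain artefacts (centre brightening). The droplet boundary is
the inflection point of the raw prebleach profile — minimum of the first
derivative after a 5-bin moving average, refined sub-bin by a local
quadratic. The boundary trace is the normalized value at the bin nearest
R − margin; "sorted" cleanup is implemented literally (ascending value sort
with time stamps kept — the multiset of values is preserved) with a
running-maximum envelope behind a flag. Imaging-induced photobleaching is
not corrected.

The inverse-variance weighting implied by azimuthal averaging (bin noise
∝ 1/√pixel-count) is available as cost weighting `"bin_counts"`
(normalized to mean one, so equal-count data reproduce the plain pooled
sum); `fit_din` uses it by default. Pooled summation over frames is the
default; per-frame weighting sits behind a flag.

## Fitting

One-parameter searches (D_in; D_out at fixed P) run Nelder–Mead in
log10-parameter space after a coarse log-grid presearch; results pinned at
the search bounds are flagged. The landscape scan fits D_out per P on a
log-spaced grid (default 15 points over [5, 5000]), warm-starting each fit
from the previous P, then refines the global minimum by a bounded
continuous minimization of the valley cost in log P between the
neighbouring grid points. The sharp-interface forward model is the default
(fast, and equivalent to the diffuse model in the thin-interface regime);
the diffuse model is available as `forward="diffuse"` and is used when the
data themselves come from a resolved-interface simulation. The forward
model's initial condition is assembled from the data: first retained frame
inside, dilute level outside.

Two regimes matter for study design, both respected by the synthetic
defaults:

- *Identifiability of D_in* requires frames that resolve the inside
  diffusion time (R²/D_in) and a window concentrated on the recovery, not
  the plateau. The round-trip fixtures use 60 frames at a fixed rate over
  ≈ 0.3 boundary-recovery times.
- *The D_out ∝ P tail* requires the dilute reservoir not to deplete at the
  largest trial P: reservoir/droplet capacity ≈ (L/R)³/P. Tail scans use
  L = 50 R so that depletion stays below ≈ 1% up to P = 1000; with the
  general-purpose default L = 10 R the valley visibly bends upward beyond
  P ≈ 300. (That same depletion is part of what makes the global minimum
  of the cost landscape unique at finite L.)

## Synthetic data

The generator solves the full model from the full-bleach state and renders
the midplane: radial interpolation onto the pixel grid, counts scaled so
the prebleach inside level is 20 000 of 65 535, camera background 100
counts, optional Gaussian blur, additive Gaussian pixel noise of
σ × (inside prebleach counts), quantization to 16 bit. Noise is additive
Gaussian rather than Poisson because camera noise dominates at these count
levels and the estimators use (weighted) least squares. Everything is
deterministic given the seed; the default fixture grid spans
P ∈ {5, 150} × D_out ∈ {0.1, 1} µm²/s at D_in = 0.01 µm²/s, R = 5 µm,
128×128 px, ≤ 60 frames — condensate- and coacervate-like conditions.

What the generator does *not* emulate: optical sectioning and refraction at
the droplet interface, fluorophore photophysics (quenching, blinking),
droplet drift, fusion or ripening, and any interfacial resistance. Passing
round-trip tests therefore demonstrates correctness of the analysis chain
under the model's own assumptions, not robustness to those effects.

## Problem sizes used in the shipped checks

Radial solves use 200–500 cells and 300–1000 time steps; landscape scans
15 P-points plus refinement (≈ 1 minute); 3D runs use 48³–64³·40 cells with
80–150 implicit steps (≈ 30–90 s each). These sizes were chosen as the
smallest at which the reported quantities are numerically converged
(doubling resolution moves them by much less than their tolerance bands).

## Known limitations

- Midplane extraction under broken vertical symmetry carries a small
  systematic: for a sessile droplet at h = R with P = 100 the fitted D_in
  is biased ≈ −5% even with fast dilute-phase diffusion, because the
  midplane disc feeds the starved lower hemisphere. The bias shrinks with
  D_out/D_in and with distance from the coverslip.
- Absolute partition coefficients from the valley are model-conditional
  (no interfacial resistance, spherical symmetry); only ratios between
  conditions should be interpreted.
- The solvers assume a stationary interface: no droplet growth, shrinkage,
  coalescence or surface-tension-driven flow.
- Uncertainty quantification (bootstrap over frames or pixels) is not
  implemented.
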