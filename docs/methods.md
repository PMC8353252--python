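# Methods

This note records the models, conventions and numerical choices behind
`poredyn`, what the synthetic generator does and does not emulate, and the
known limitations.

## Channel frame

All analyses work in a channel-centred frame defined per stored frame.

- **Axis.** The channel axis is the largest-variance eigendirection of the
  centred second-moment tensor of the backbone particle group, sign-aligned
  frame to frame (the dot product of consecutive directions is kept
  positive) so the axis never flips.  A laboratory-fixed axis can be
  supplied instead (`lab_axis`); the fitted axis is the default because it
  is robust to channel tilt in a membrane.
- **Origin and z.** The origin sits on the axis at the axial midpoint of
  the backbone projection, so the axial coordinate z is midpoint-centred.
  The pore's axial bounds are the backbone extent ± `z_pad`.
- **θ reference.** The θ = 0 direction is the transverse component of a
  designated reference particle (default: the first backbone particle),
  recomputed per frame.  This makes the frame co-rotate with the tube:
  angular density lobes stay registered even when the channel rotates about
  its axis, which is what makes long-time-averaged transverse maps sharp
  rather than smeared.  A point on the axis has θ = 0 by convention
  (numerically, R ≤ 1e−9 Å).

Coordinates are Å and times ps throughout; MDAnalysis performs the nm→Å
conversion for GRO-family inputs.

## Residency and occupancy

A tracked particle is inside the pore at frame f iff R ≤ `pore_radius` and
z_lo[f] ≤ z ≤ z_hi[f].  The pore radius is an explicit configuration value,
not inferred from data.  Water is represented by its oxygen position, ions
by the ion position.  The default analysis window discards the first 10% of
frames (configurable), matching common practice of excluding the
equilibration transient.

## Survival probability

P(τ) is the average over time origins of N(t, t+τ)/N(t).  Two conventions
are implemented:

- **continuous** (default): a particle survives a lag τ only if it is
  inside at *every* stored frame in [t, t+τ].  This is the standard strict
  residence convention and guarantees a non-increasing curve.
- **intermittent**: survival requires presence only at the two endpoints,
  so brief excursions do not terminate residence.

A single common origin set is used for the whole curve: origins t with
t + τ_max ≤ T and N(t) > 0.  With a fixed origin set every per-origin ratio
is non-increasing in τ under the continuous convention, so the averaged
curve is monotone with P(0) = 1 by construction; letting the origin set
grow with decreasing τ (all t with t + τ ≤ T) can produce spurious upticks
on short trajectories when late origins drop out of the average.  Origins
with N(t) = 0 contribute nothing and are excluded rather than counted as
zeros, which is what keeps P(0) exactly 1.

τ1/2 is read off by linear interpolation between the two grid points
bracketing P = 0.5 and reported as undefined (not an error) when the curve
never reaches 0.5 within the grid.

## Windowed velocities

Mean velocity over a window is the unwrapped displacement divided by the
window length, tagged with the start-of-window position (Cartesian and
cylindrical).  Unwrapping accumulates minimum-image displacements between
consecutive frames, which assumes no particle travels more than half a box
length per stored frame.  Windows are non-overlapping by default (stride =
window) to avoid autocorrelated samples; the stride is configurable.  A
window is kept only if the particle is inside the pore at every frame it
spans, so bulk motion never enters in-pore statistics.  The default window
of 10 ps matches the saved-frame spacing typical of the production
trajectories these analyses target.

Speed histograms use the Freedman–Diaconis rule, w = 2·IQR·n^(−1/3), with
the linear-interpolation quantile convention (the rule is
convention-sensitive, so the convention is fixed and tested against an
independent quantile routine).  Degenerate inputs fall back in order: zero
IQR → Scott-like 3.49·σ·n^(−1/3); zero σ → a single bin.

## Density maps

Maps accumulate inside-particle positions in the co-rotating channel frame
and divide by the total inside count, so every map is a probability
distribution (cells sum to 1).  (R, θ) maps report raw count fractions with
no 1/R Jacobian correction — they answer "where is the particle" rather
than "what is the local number density"; a Jacobian-corrected variant is
available by flag.  The default planar bin width is 0.25 Å, fine enough to
resolve ~1 Å angular lobes at the sampling depth of 10⁴-frame trajectories.

## RDF, coordination, H-bonds

g_c(r) for contributor class c around inside centers is the shell pair
count divided by n_centers · n_contributors_c · (shell volume / box
volume), averaged over window frames with at least one inside center, with
minimum-image distances.  This normalisation gives g → 1 for an ideal gas,
and every factor is recorded in the profile metadata so alternative
normalisations are recomputable.  The first-shell radius is the first local
minimum after the first peak above 1 of a lightly smoothed g(r) (3-point
moving average by default; raw g(r) noise creates spurious minima).
Coordination numbers count contributors within the shell radius per
(frame, center) observation; the SD is over those observations.  The
integration route Σ g(r)·ρ·shell_vol over bins up to the shell radius is
the exact inverse of the RDF normalisation and serves as an independent
cross-check of direct counting.

H-bonds use the common geometric criterion — donor–acceptor distance
≤ 3.5 Å and donor–hydrogen–acceptor angle (at the hydrogen) ≥ 150° — both
configurable.  The theoretical inter-ring maximum for a stacked-ring tube
is (n_rings − 1) · bonds_per_interface: one interface per adjacent ring
pair, each saturated.

## Synthetic generator

The generator provides ground truth, not force-field realism.  Particles
follow overdamped Langevin dynamics

    x ← x + D·F(x)·dt + ∇D·dt + √(2·D·dt)·ξ

with energies in units of kT (β = 1) and F = −∇U.  The potential is

    U = ½·k_wall·max(0, R − R₀)²  +  a_θ·(R/R₀)^m·cos(mθ)  +  a_z·cos(2πz/p)

where the angular term is the harmonic polynomial Re[((x+iy)/R₀)^m] —
smooth at the axis with an analytic gradient.  Defaults mirror an
eight-ring stacked-peptide channel: R₀ = 9 Å, length 8 × 4.9 = 39.2 Å,
harmonic order m = 6, axial period p = 4.9 Å, D = 0.23 Å²/ps (bulk-water
scale), dt = 0.02 ps, frames saved every 1 ps.  Modulation amplitudes
default to zero and are switched on per study.  z is periodic by default
(reflective caps by flag).

Numerical safeguards: the run refuses timesteps whose typical wall
pull-back displacement D·dt·k_wall·√(2·D·dt) exceeds 0.5 Å; a hard
reflective cap at R₀ + 3√(2·D·dt) bounds every saved radial position
regardless of parameters (with the default k_wall = 150 kT/Å² the soft wall
keeps penetration well inside the cap, so the cap is almost never
exercised).  Position-dependent mobility (reduced D near the wall) includes
the Itô ∇D drift so the stationary distribution remains Boltzmann.

Two further generators close the loop: an alternating exponential
outside/inside dwell process (frame-sampled flags plus exact continuous
intervals, half-life ln 2/λ_out in closed form), and a rejection sampler of
exp(−U) over the pore volume plus the soft-wall penetration skin
(R ≤ R₀ + 5/√k_wall), which is the exact equilibrium density the Brownian
dynamics should reproduce.

**What the generator does not emulate:** electrostatics and ion–ion
correlations, hydrogen-bond network structure, lipid membranes, inertial
(ballistic) motion, and force-field-specific coordination chemistry.
Passing tests therefore demonstrate that the estimators recover known
statistical structure — diffusive scaling, exponential residence, six-fold
density modulation, ideal-gas RDF limits — not that any particular chemical
system behaves this way.

## Problem sizes

Validation runs are sized for single-CPU execution: the star-recovery check
uses 2,000 Brownian particles × 150 ps (3 × 10⁵ map samples) against
3 × 10⁵ Boltzmann samples on a 6 × 12 (R, θ) grid, where sampling noise
contributes ≈ 0.02 total-variation distance; half-life recovery uses ≥
2,000 dwell events; RDF fixtures use ~10³ contributors over tens of frames.

## Known limitations

- Orthorhombic boxes only; no triclinic support.
- Axis fitting assumes the backbone's long axis is its largest-variance
  direction; a severely fragmented channel would need an external axis.
- The survival estimator's common-origin-set convention discards origins in
  the final τ_max of the trajectory; for τ_max ≪ T the loss is negligible.
- Unwrapping assumes displacements below half a box length per stored
  frame.
- H-bond classification labels require residue metadata the plain-text
  fixture dialect does not carry; counts are always available, labels only
  on annotated inputs.
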