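# poredyn

Analysis of confined water and ion dynamics inside cylindrical transmembrane
channels — self-assembled cyclic peptide nanotubes (SCPNs) and similar
stacked-ring pores — from molecular dynamics trajectories.

Simulations of these channels show strongly structured behaviour of the
confined species: water arranges into a six-lobed "star" pattern in the
transverse plane, densities alternate between ring planes and inter-ring
regions along the axis, and each ionic species has its own residence time
and mobility inside the pore. `poredyn` provides the statistics used to
characterise that behaviour, plus a synthetic confined-Brownian generator
with known ground truth so every estimator can be validated without
multi-hundred-nanosecond trajectories.

## What it computes

- **Pore residency and occupancy** — a per-frame inside/outside matrix from
  a cylinder criterion (R ≤ pore radius, z within the channel bounds) on a
  per-frame fitted channel axis; occupancy means/SDs, per-particle z-traces
  and z-presence histograms.
- **Survival probability and residence half-life** — the time-origin
  average

      P(τ) = ⟨ N(t, t+τ) / N(t) ⟩_t

  where N(t) is the number of tracked particles inside the pore at time t
  and N(t, t+τ) how many of those are still inside after a lag τ (strict
  continuous residence by default).  The residence half-life τ1/2 is the
  lag at which P crosses 0.5.
- **Windowed velocities** — finite-difference mean velocities over fixed
  windows (default 10 ps) fully inside the pore, on unwrapped coordinates;
  speed distributions with Freedman–Diaconis bin widths
  (w = 2·IQR·n^(−1/3)); position–velocity correlation on an (R, θ) grid.
- **2D positional probability maps** — XY/XZ/YZ and (R, θ) heatmaps of
  inside-particle positions in a co-rotating channel frame, normalised to
  total inside counts.
- **RDF decomposition and coordination** — g(r) per contributor species
  around inside centers with ideal-gas normalisation, first-shell radius
  from the first post-peak minimum, coordination numbers as mean ± SD
  contacts, cross-checkable against 4πρ∫g(r)r²dr.
- **H-bond inventories** — geometric criterion (D···A ≤ 3.5 Å,
  D–H···A ≥ 150°), and the theoretical inter-ring maximum
  (n_rings − 1)·bonds_per_interface for a stacked-ring tube.
- **Synthetic trajectories** — overdamped Langevin particles in a
  star-modulated cylindrical pore (six-fold angular and ring-period axial
  modulation), an exponential dwell process for residence statistics, and a
  direct Boltzmann sampler of the same potential.

Real trajectories load through MDAnalysis (GRO/PDB topology + XTC/TRR/DCD
frames); a plain-text fixture dialect covers dependency-free testing.

## Worked example

Residence half-life recovery on synthetic dwell kinetics
(`examples/01_survival_half_life.py`):

```python
from poredyn import DwellProcessParams, simulate_dwell_process, survival_probability

params = DwellProcessParams(entry_rate=0.02, exit_rate=0.05,
                            n_particles=150, duration=2000.0, seed=1)
residency, truth = simulate_dwell_process(params)
curve = survival_probability(residency, tau_max=60.0)
```

prints

```
dwell events generated : 4297
P(tau) at 0/10/20 ps   : 1.000 0.613 0.377
residence half-life    : 14.21 ps
exact ln2/lambda       : 13.86 ps
```

The dwell process leaves the pore at rate λ_out = 0.05 ps⁻¹, so the exact
half-life is ln 2/λ_out ≈ 13.86 ps; the estimate recovered from the sampled
residency matrix lands within a few percent (frame-grid discretisation plus
finite sampling).  The other scripts in `examples/` demonstrate the
six-point-star density map, RDF/coordination analysis, H-bond counting and
the config-driven pipeline; each prints the numbers it computes and what
they mean.

A thin CLI wraps the pipeline for shell use:

```bash
poredyn all --config analysis.yaml --seed 7 --outdir results/
```

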