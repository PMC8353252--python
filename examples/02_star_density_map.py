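"""Six-point-star density map from confined Brownian dynamics.

Runs Brownian particles in a cylindrical pore whose potential has a
six-fold angular modulation, fits the channel axis from the synthetic
backbone scaffold, classifies pore residency, and builds the (R, θ)
positional probability map.  The angular Fourier spectrum of the θ-marginal
should peak at harmonic 6 — the transverse star pattern of nanoconfined
water in a stacked-ring channel.
"""

import numpy as np

from poredyn import (PoreModelParams, classify_inside, cylindrical_heatmap,
                     fit_channel_axis, simulate_confined_brownian)

params = PoreModelParams(angular_amplitude=1.5, axial_amplitude=0.5, seed=2)
traj, truth = simulate_confined_brownian(params, n_particles=300,
                                         duration=100.0, init="boltzmann")
geom = fit_channel_axis(traj, "backbone", pore_radius=params.pore_radius,
                        z_pad=1.0)
res = classify_inside(traj, geom, "mobile")
dmap = cylindrical_heatmap(traj, res, geom, r_bins=6, theta_bins=24,
                           window_start=10.0)

theta_marginal = dmap.probability.sum(axis=0)
amp = np.abs(np.fft.rfft(theta_marginal - theta_marginal.mean()))
dominant = int(np.argmax(amp[1:13]) + 1)

print(f"map cells              : {dmap.probability.shape}, "
      f"total probability {dmap.probability.sum():.6f}")
print(f"dominant θ harmonic    : {dominant} (generator truth: "
      f"{truth.harmonic_order})")
print(f"θ-marginal min/max     : {theta_marginal.min():.4f} / "
      f"{theta_marginal.max():.4f}")
# Harmonic 6 means the confined density forms six angular lobes, the
# star-shaped ordering the map is designed to resolve.
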