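"""Synthetic confined-Brownian trajectories with known ground truth.

Stand-in for all-atom MD production runs of water and ions inside a
transmembrane channel: particles follow overdamped Langevin dynamics in a
cylindrical pore whose potential carries a six-fold angular modulation (the
"six-point star" of nanoconfined water in the transverse plane) and an
axial modulation with the ring-stacking period (~4.9 Å), so every analysis
stage of the pipeline has a generator with analytically known structure.
Dwell kinetics (pore entry/exit) are modelled separately as an alternating
renewal process with exponential waiting times, giving a closed-form
residence half-life ln 2 / λ_out for survival-curve validation.

All energies are expressed in units of kT (β = 1), so the overdamped update
reads  x ← x + D·F(x)·dt + ∇D·dt + √(2·D·dt)·ξ  with F = −∇U; the ∇D term
is the Itô drift required for the correct stationary distribution when the
mobility depends on position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .occupancy import ResidencyMatrix
from .trajectory import Trajectory

__all__ = [
    "PoreModelParams",
    "DwellProcessParams",
    "SyntheticGroundTruth",
    "simulate_confined_brownian",
    "simulate_dwell_process",
    "generate_star_reference_density",
]


@dataclass
class PoreModelParams:
    """Parameters of the star-modulated cylindrical pore model.

    Units: Å for lengths, ps for times, Å²/ps for diffusion, kT for energies.
    The default geometry mirrors an eight-ring stacked-peptide channel
    (8 planes at 4.9 Å spacing, ~9 Å pore radius) but is an explicit
    stand-in with no claim of force-field realism.
    """

    pore_radius: float = 9.0
    pore_length: float = 8 * 4.9
    wall_stiffness: float = 150.0         # kT/Å² beyond the pore radius
    angular_amplitude: float = 0.0        # kT, depth of the cos(kθ) modulation
    harmonic_order: int = 6
    axial_amplitude: float = 0.0          # kT, cos(2πz/period) modulation
    axial_period: float = 4.9
    diffusion: float = 0.23               # Å²/ps (bulk-water-like default)
    wall_mobility_factor: float = 1.0     # D at the wall relative to the axis
    timestep: float = 0.02                # ps
    save_interval: float = 1.0            # ps
    periodic_z: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.pore_radius, self.pore_length, self.timestep,
               self.save_interval) <= 0:
            raise ValueError("radius, length, timestep, save interval must be > 0")
        if self.harmonic_order < 1:
            raise ValueError("harmonic_order must be ≥ 1")
        if not (0 < self.wall_mobility_factor <= 1):
            raise ValueError("wall_mobility_factor must be in (0, 1]")


@dataclass
class DwellProcessParams:
    """Alternating outside/inside renewal process with exponential waits."""

    entry_rate: float = 0.02      # λ_in, 1/ps
    exit_rate: float = 0.05       # λ_out, 1/ps
    n_particles: int = 50
    duration: float = 2000.0      # ps
    dt_saved: float = 1.0         # ps frame grid
    seed: int = 0

    def __post_init__(self) -> None:
        if self.entry_rate <= 0 or self.exit_rate <= 0:
            raise ValueError("rates must be positive")


@dataclass
class SyntheticGroundTruth:
    """What the generator knows to be true about its output."""

    diffusion: float | None = None
    dwell_exit_rate: float | None = None
    dwell_entry_rate: float | None = None
    angular_amplitude: float | None = None
    harmonic_order: int | None = None
    axial_period: float | None = None
    inside_intervals: dict[int, list[tuple[float, float]]] = field(
        default_factory=dict)
    n_dwell_events: int = 0
    warnings: list[str] = field(default_factory=list)
    seed: int | None = None


def _potential_force(pos: np.ndarray, p: PoreModelParams
                     ) -> tuple[np.ndarray, np.ndarray]:
    """U (kT) and F = −∇U at pore-centred coordinates (axis along z)."""
    x, y, z = pos[:, 0], pos[:, 1], pos[:, 2]
    R = np.hypot(x, y)
    U = np.zeros(len(pos))
    F = np.zeros_like(pos)

    # soft wall
    over = R - p.pore_radius
    mask = over > 0
    if mask.any():
        U[mask] += 0.5 * p.wall_stiffness * over[mask] ** 2
        with np.errstate(invalid="ignore"):
            scale = np.where(R > 0, p.wall_stiffness * over / R, 0.0)
        F[mask, 0] -= scale[mask] * x[mask]
        F[mask, 1] -= scale[mask] * y[mask]

    # angular modulation as the harmonic polynomial Re[(x+iy)^m]/R0^m,
    # smooth at the axis with analytic gradient
    if p.angular_amplitude != 0.0:
        m = p.harmonic_order
        w = (x + 1j * y) / p.pore_radius
        U += p.angular_amplitude * np.real(w ** m)
        grad = p.angular_amplitude * m * w ** (m - 1) / p.pore_radius
        F[:, 0] -= np.real(grad)
        F[:, 1] -= -np.imag(grad)

    # axial modulation
    if p.axial_amplitude != 0.0:
        k = 2 * np.pi / p.axial_period
        U += p.axial_amplitude * np.cos(k * z)
        F[:, 2] += p.axial_amplitude * k * np.sin(k * z)

    return U, F


def _mobility(pos: np.ndarray, p: PoreModelParams
              ) -> tuple[np.ndarray, np.ndarray]:
    """Position-dependent D(R) and its Cartesian gradient (Itô drift).

    D decreases quadratically from the axis value to wall_mobility_factor·D
    at the pore radius, constant beyond.
    """
    if p.wall_mobility_factor == 1.0:
        n = len(pos)
        return np.full(n, p.diffusion), np.zeros((n, 3))
    x, y = pos[:, 0], pos[:, 1]
    R = np.hypot(x, y)
    frac = np.minimum(R / p.pore_radius, 1.0)
    drop = (1.0 - p.wall_mobility_factor)
    D = p.diffusion * (1.0 - drop * frac ** 2)
    dDdR = np.where(R < p.pore_radius,
                    -2.0 * p.diffusion * drop * R / p.pore_radius ** 2, 0.0)
    grad = np.zeros_like(pos)
    with np.errstate(invalid="ignore"):
        unit = np.where(R[:, None] > 0, pos[:, :2] / R[:, None], 0.0)
    grad[:, :2] = dDdR[:, None] * unit
    return D, grad


def _check_stability(p: PoreModelParams) -> None:
    # typical single-step wall penetration and the resulting force pull-back
    step = np.sqrt(2 * p.diffusion * p.timestep)
    pull = p.diffusion * p.timestep * p.wall_stiffness * step
    if pull > 0.5:
        raise ValueError(
            f"timestep too large: wall displacement per step {pull:.2f} Å "
            "exceeds 0.5 Å; reduce timestep or wall stiffness")


def _synthetic_backbone(p: PoreModelParams, n_rings: int = 8,
                        atoms_per_ring: int = 12) -> np.ndarray:
    """Static scaffold rings at the ring-plane z positions (pore-centred)."""
    z_planes = (np.arange(n_rings) - (n_rings - 1) / 2) * p.axial_period
    angles = 2 * np.pi * np.arange(atoms_per_ring) / atoms_per_ring
    pts = []
    for z in z_planes:
        for a in angles:
            pts.append([p.pore_radius * np.cos(a),
                        p.pore_radius * np.sin(a), z])
    return np.array(pts)


def simulate_confined_brownian(params: PoreModelParams, n_particles: int,
                               duration: float,
                               init: str = "uniform",
                               species: str = "mobile",
                               include_backbone: bool = True
                               ) -> tuple[Trajectory, SyntheticGroundTruth]:
    """Simulate overdamped Brownian particles in the star-modulated pore.

    ``init`` is ``"uniform"`` (uniform in the inner 80% of the pore) or
    ``"boltzmann"`` (equilibrium start via rejection sampling, useful when
    every saved frame should be equilibrium-distributed).  The returned
    trajectory embeds the pore in an orthorhombic box (axis along z through
    the box centre) and, by default, a static synthetic backbone scaffold
    group for axis fitting.  Same seed → bitwise-identical output.
    """
    p = params
    if duration < 10 * p.save_interval:
        raise ValueError("duration must be ≥ 10 × save interval")
    _check_stability(p)
    rng = np.random.default_rng(p.seed)
    n_sub = int(round(p.save_interval / p.timestep))
    if abs(n_sub * p.timestep - p.save_interval) > 1e-9:
        raise ValueError("save_interval must be a multiple of timestep")
    n_saved = int(round(duration / p.save_interval)) + 1
    dt = p.timestep
    L = p.pore_length

    if init == "boltzmann":
        pos = _boltzmann_samples(p, n_particles, rng)
    else:
        R = 0.8 * p.pore_radius * np.sqrt(rng.random(n_particles))
        th = rng.uniform(-np.pi, np.pi, n_particles)
        z = rng.uniform(-L / 2, L / 2, n_particles)
        pos = np.column_stack([R * np.cos(th), R * np.sin(th), z])

    # hard reflective cap just beyond the soft wall: guarantees every saved
    # radial position obeys R ≤ pore_radius + 3·√(2·D·dt) regardless of the
    # wall stiffness; with the default stiffness it is almost never touched
    r_cap = p.pore_radius + 3 * np.sqrt(2 * p.diffusion * p.timestep)

    saved = np.empty((n_saved, n_particles, 3))
    saved[0] = pos
    for s in range(1, n_saved):
        for _ in range(n_sub):
            _, F = _potential_force(pos, p)
            D, gradD = _mobility(pos, p)
            noise = rng.standard_normal((n_particles, 3))
            pos = (pos + (D[:, None] * F + gradD) * dt
                   + np.sqrt(2 * D[:, None] * dt) * noise)
            if p.wall_stiffness > 0:
                R = np.hypot(pos[:, 0], pos[:, 1])
                over = R > r_cap
                if over.any():
                    scale = (2 * r_cap - R[over]) / R[over]
                    pos[over, 0] *= scale
                    pos[over, 1] *= scale
            if p.periodic_z:
                pos[:, 2] = (pos[:, 2] + L / 2) % L - L / 2
            else:
                # reflective caps
                z = pos[:, 2]
                z = np.where(z > L / 2, L - z, z)
                z = np.where(z < -L / 2, -L - z, z)
                pos[:, 2] = z
        saved[s] = pos

    box = np.array([4 * p.pore_radius, 4 * p.pore_radius, L])
    shift = box / 2
    groups = {species: np.arange(n_particles)}
    if include_backbone:
        bb = _synthetic_backbone(p)
        bb_block = np.tile(bb + shift, (n_saved, 1, 1))
        saved_lab = np.concatenate([saved + shift, bb_block], axis=1)
        groups["backbone"] = n_particles + np.arange(len(bb))
    else:
        saved_lab = saved + shift

    times = p.save_interval * np.arange(n_saved)
    traj = Trajectory(saved_lab, times, np.tile(box, (n_saved, 1)),
                      groups=groups)

    # inside intervals from the saved frames (R ≤ pore radius)
    Rs = np.hypot(saved[:, :, 0], saved[:, :, 1])
    inside = Rs <= p.pore_radius
    intervals: dict[int, list[tuple[float, float]]] = {}
    for i in range(n_particles):
        intervals[i] = _flags_to_intervals(inside[:, i], times)

    truth = SyntheticGroundTruth(
        diffusion=p.diffusion, angular_amplitude=p.angular_amplitude,
        harmonic_order=p.harmonic_order, axial_period=p.axial_period,
        inside_intervals=intervals, seed=p.seed)
    return traj, truth


def _flags_to_intervals(flags: np.ndarray,
                        times: np.ndarray) -> list[tuple[float, float]]:
    out = []
    start = None
    for f, on in enumerate(flags):
        if on and start is None:
            start = times[f]
        elif not on and start is not None:
            out.append((float(start), float(times[f - 1])))
            start = None
    if start is not None:
        out.append((float(start), float(times[-1])))
    return out


def simulate_dwell_process(params: DwellProcessParams
                           ) -> tuple[ResidencyMatrix, SyntheticGroundTruth]:
    """Alternating exponential outside/inside process sampled on a frame grid.

    Each particle starts outside, waits Exp(λ_in), stays inside Exp(λ_out),
    and repeats.  True continuous intervals are recorded in the ground
    truth; the residency matrix holds the frame-sampled flags.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n_frames = int(round(p.duration / p.dt_saved)) + 1
    times = p.dt_saved * np.arange(n_frames)
    inside = np.zeros((p.n_particles, n_frames), dtype=bool)
    intervals: dict[int, list[tuple[float, float]]] = {}
    n_events = 0

    for i in range(p.n_particles):
        t = 0.0
        ivs: list[tuple[float, float]] = []
        while t < p.duration:
            t += rng.exponential(1.0 / p.entry_rate)
            if t >= p.duration:
                break
            dwell = rng.exponential(1.0 / p.exit_rate)
            t_exit = min(t + dwell, p.duration)
            ivs.append((t, t_exit))
            n_events += 1
            lo = int(np.ceil(t / p.dt_saved))
            hi = int(np.floor(t_exit / p.dt_saved))
            if hi >= lo:
                inside[i, lo:hi + 1] = True
            t = t_exit
        intervals[i] = ivs

    truth = SyntheticGroundTruth(
        dwell_exit_rate=p.exit_rate, dwell_entry_rate=p.entry_rate,
        inside_intervals=intervals, n_dwell_events=n_events, seed=p.seed)
    if n_events < 50:
        truth.warnings.append(
            f"only {n_events} dwell events; statistics will be poor")
    res = ResidencyMatrix(np.arange(p.n_particles), inside, times)
    return res, truth


def _boltzmann_samples(p: PoreModelParams, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample exp(−U) over the pore cylinder plus the soft-wall
    penetration skin, so the support matches the Brownian dynamics."""
    if p.wall_stiffness > 0:
        r_max = p.pore_radius + 5.0 / np.sqrt(p.wall_stiffness)
    else:
        r_max = p.pore_radius
    u_min = (-abs(p.angular_amplitude) * (r_max / p.pore_radius)
             ** p.harmonic_order - abs(p.axial_amplitude))
    out = np.empty((0, 3))
    n_tried = 0
    while len(out) < n:
        batch = max(4 * (n - len(out)), 1000)
        R = r_max * np.sqrt(rng.random(batch))
        th = rng.uniform(-np.pi, np.pi, batch)
        z = rng.uniform(-p.pore_length / 2, p.pore_length / 2, batch)
        cand = np.column_stack([R * np.cos(th), R * np.sin(th), z])
        U, _ = _potential_force(cand, p)
        accept = rng.random(batch) < np.exp(-(U - u_min))
        out = np.vstack([out, cand[accept]])
        n_tried += batch
        if n_tried > 1000 and len(out) / n_tried < 1e-4:
            raise ValueError("rejection acceptance rate below 1e-4; "
                             "modulation amplitudes too large")
    return out[:n]


def generate_star_reference_density(params: PoreModelParams, n_samples: int,
                                    seed: int | None = None) -> np.ndarray:
    """Direct Boltzmann samples of the pore potential (pore-centred coords).

    Rejection sampling from exp(−U(R, θ, z)) inside the pore volume; the
    exact equilibrium density the Brownian simulator should converge to.
    Same seed → identical samples.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be ≥ 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    return _boltzmann_samples(params, n_samples, rng)
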