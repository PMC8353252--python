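"""Windowed velocity estimation and position–velocity correlation.

Velocities are finite-difference estimates over fixed time windows
(default 10 ps): the mean velocity over a window is the unwrapped
displacement divided by the window length, tagged with the start-of-window
position in both Cartesian and channel cylindrical coordinates.  A window is
kept only if the particle is inside the pore at every frame it spans, so
bulk motion never contaminates in-pore statistics.  Speed histograms use the
Freedman–Diaconis bin-width rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .occupancy import ResidencyMatrix
from .trajectory import ChannelGeometry, Trajectory, to_cylindrical, unwrap_positions

__all__ = [
    "VelocitySamples",
    "SpeedHistogram",
    "PositionVelocityMap",
    "windowed_velocities",
    "freedman_diaconis_binwidth",
    "speed_distribution",
    "position_velocity_correlation",
]


@dataclass
class VelocitySamples:
    """Per-window velocity samples.

    Arrays are parallel over samples: particle id, window start time (ps),
    start position (Cartesian, Å), start position (R, θ, z), mean velocity
    vector (Å/ps) and speed (Å/ps).  ``window`` is the window length in ps.
    """

    particle_ids: np.ndarray
    t_start: np.ndarray
    xyz: np.ndarray
    R: np.ndarray
    theta: np.ndarray
    z: np.ndarray
    velocity: np.ndarray
    speed: np.ndarray
    window: float

    @property
    def n_samples(self) -> int:
        return self.speed.size


@dataclass
class SpeedHistogram:
    """Normalized speed histogram; probabilities sum to 1."""

    edges: np.ndarray
    probability: np.ndarray
    rule: str  # "freedman-diaconis" | "scott-fallback" | "single-bin"


@dataclass
class PositionVelocityMap:
    """(R, θ) occupancy plus binned speed distributions per R and per θ bin."""

    r_edges: np.ndarray
    theta_edges: np.ndarray
    occupancy: np.ndarray          # (r_bins, theta_bins), sums to 1
    speed_edges: np.ndarray
    speed_by_r: np.ndarray         # (r_bins, speed_bins) counts
    speed_by_theta: np.ndarray     # (theta_bins, speed_bins) counts
    mean_speed_by_r: np.ndarray
    mean_speed_by_theta: np.ndarray


def windowed_velocities(traj: Trajectory, res: ResidencyMatrix,
                        geom: ChannelGeometry, window: float,
                        discard: float = 0.0,
                        stride: float | None = None) -> VelocitySamples:
    """Mean velocities over fixed windows fully inside the pore.

    ``window`` and ``stride`` (default = window, i.e. non-overlapping) must
    be multiples of the frame spacing; frames before ``discard`` ps are
    skipped.  Displacements are taken on unwrapped coordinates so periodic
    wrapping never corrupts the estimate.
    """
    dt = traj.dt_saved
    if dt <= 0:
        raise ValueError("trajectory needs at least two frames")
    k = int(round(window / dt))
    if k < 1 or abs(k * dt - window) > 1e-6 * dt:
        raise ValueError("window must be a positive multiple of frame spacing")
    stride = window if stride is None else stride
    sk = int(round(stride / dt))
    if sk < 1 or abs(sk * dt - stride) > 1e-6 * dt:
        raise ValueError("stride must be a positive multiple of frame spacing")
    if discard >= traj.times[-1]:
        raise ValueError("discard exceeds the trajectory span")

    unwrapped = unwrap_positions(traj)
    first = int(np.searchsorted(traj.times, traj.times[0] + discard))
    starts = np.arange(first, traj.n_frames - k, sk, dtype=np.intp)

    ids_out, t_out, xyz_out, vel_out = [], [], [], []
    cyl_cache: dict[int, object] = {}
    for i, pid in enumerate(res.particle_ids):
        flags = res.inside[i]
        for s in starts:
            if not flags[s:s + k + 1].all():
                continue
            disp = unwrapped[s + k, pid] - unwrapped[s, pid]
            ids_out.append(pid)
            t_out.append(traj.times[s])
            xyz_out.append((traj.positions[s, pid], s))
            vel_out.append(disp / window)

    if not vel_out:
        return VelocitySamples(
            particle_ids=np.empty(0, dtype=np.intp), t_start=np.empty(0),
            xyz=np.empty((0, 3)), R=np.empty(0), theta=np.empty(0),
            z=np.empty(0), velocity=np.empty((0, 3)), speed=np.empty(0),
            window=float(window))

    velocity = np.array(vel_out)
    xyz = np.array([p for p, _ in xyz_out])
    frames = np.array([f for _, f in xyz_out], dtype=np.intp)
    R = np.empty(len(xyz))
    theta = np.empty(len(xyz))
    z = np.empty(len(xyz))
    for f in np.unique(frames):
        m = frames == f
        cyl = to_cylindrical(xyz[m], geom, int(f))
        R[m], theta[m], z[m] = cyl.R, cyl.theta, cyl.z

    return VelocitySamples(
        particle_ids=np.array(ids_out, dtype=np.intp),
        t_start=np.array(t_out), xyz=xyz, R=R, theta=theta, z=z,
        velocity=velocity, speed=np.linalg.norm(velocity, axis=1),
        window=float(window))


def freedman_diaconis_binwidth(samples: np.ndarray) -> float:
    """Freedman–Diaconis bin width 2·IQR·n^(−1/3).

    The IQR uses the linear-interpolation quantile convention.  If the IQR is
    zero the width falls back to the Scott-like 3.49·σ·n^(−1/3); if that is
    also zero (constant data) 0.0 is returned, signalling a single bin.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples for a bin width")
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    n = x.size
    if iqr > 0:
        return float(2.0 * iqr * n ** (-1.0 / 3.0))
    sd = x.std()
    if sd > 1e-12 * max(1.0, float(np.abs(x).max())):
        return float(3.49 * sd * n ** (-1.0 / 3.0))
    return 0.0


def _fd_histogram(values: np.ndarray) -> SpeedHistogram:
    width = freedman_diaconis_binwidth(values)
    lo, hi = float(values.min()), float(values.max())
    if width == 0.0 or hi == lo:
        edges = np.array([lo - 0.5, lo + 0.5]) if hi == lo else np.array([lo, hi])
        prob = np.array([1.0])
        return SpeedHistogram(edges=edges, probability=prob, rule="single-bin")
    n_bins = max(1, int(np.ceil((hi - lo) / width)))
    edges = lo + width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi)  # guard float rounding at the top edge
    counts, edges = np.histogram(values, bins=edges)
    rule = "freedman-diaconis" if np.percentile(values, 75) > np.percentile(values, 25) \
        else "scott-fallback"
    return SpeedHistogram(edges=edges, probability=counts / counts.sum(), rule=rule)


def speed_distribution(vel: VelocitySamples) -> SpeedHistogram:
    """Normalized speed histogram with the Freedman–Diaconis bin width."""
    if vel.n_samples < 2:
        raise ValueError("need at least 2 velocity samples")
    return _fd_histogram(vel.speed)


def position_velocity_correlation(vel: VelocitySamples, r_bins: int,
                                  theta_bins: int) -> PositionVelocityMap:
    """(R, θ) occupancy of sample start positions and binned speed
    distributions per radial and per angular bin."""
    if vel.n_samples == 0:
        raise ValueError("no velocity samples")
    if r_bins < 1 or theta_bins < 1:
        raise ValueError("bin counts must be ≥ 1")
    r_edges = np.linspace(0.0, float(vel.R.max()) * (1 + 1e-9) or 1.0, r_bins + 1)
    theta_edges = np.linspace(-np.pi, np.pi, theta_bins + 1)
    occ, _, _ = np.histogram2d(vel.R, vel.theta, bins=[r_edges, theta_edges])
    occupancy = occ / occ.sum()

    sh = _fd_histogram(vel.speed)
    speed_edges = sh.edges
    n_s = speed_edges.size - 1
    speed_by_r = np.zeros((r_bins, n_s))
    speed_by_theta = np.zeros((theta_bins, n_s))
    mean_r = np.full(r_bins, np.nan)
    mean_t = np.full(theta_bins, np.nan)

    r_idx = np.clip(np.searchsorted(r_edges, vel.R, side="right") - 1, 0, r_bins - 1)
    t_idx = np.clip(np.searchsorted(theta_edges, vel.theta, side="right") - 1,
                    0, theta_bins - 1)
    for b in range(r_bins):
        m = r_idx == b
        if m.any():
            speed_by_r[b], _ = np.histogram(vel.speed[m], bins=speed_edges)
            mean_r[b] = vel.speed[m].mean()
    for b in range(theta_bins):
        m = t_idx == b
        if m.any():
            speed_by_theta[b], _ = np.histogram(vel.speed[m], bins=speed_edges)
            mean_t[b] = vel.speed[m].mean()

    return PositionVelocityMap(
        r_edges=r_edges, theta_edges=theta_edges, occupancy=occupancy,
        speed_edges=speed_edges, speed_by_r=speed_by_r,
        speed_by_theta=speed_by_theta, mean_speed_by_r=mean_r,
        mean_speed_by_theta=mean_t)
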