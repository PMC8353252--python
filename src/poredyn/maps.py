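"""2D positional probability heatmaps in the channel-aligned frame.

Maps are built from inside-particle positions only, expressed in the
co-rotating channel frame (transverse components x, y along the angular
reference basis; axial component z), and normalized by the total number of
inside counts so every map is a probability distribution.  Cylindrical
(R, θ) maps report raw count fractions by default — no 1/R Jacobian
correction — matching positional-probability semantics; a corrected variant
is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .occupancy import ResidencyMatrix
from .trajectory import ChannelGeometry, ConfigurationError, Trajectory

__all__ = ["DensityMap2D", "planar_heatmap", "cylindrical_heatmap",
           "backbone_overlay"]

_PLANES = {"XY": (0, 1), "XZ": (0, 2), "YZ": (1, 2)}


@dataclass
class DensityMap2D:
    """Probability per cell on a 2D grid, with optional overlay point sets."""

    plane: str                      # XY | XZ | YZ | R-theta
    x_edges: np.ndarray
    y_edges: np.ndarray
    probability: np.ndarray         # (nx, ny), sums to 1
    overlays: dict[str, np.ndarray] | None = None


def _channel_frame_coords(traj: Trajectory, geom: ChannelGeometry,
                          ids: np.ndarray, frames: np.ndarray) -> np.ndarray:
    """(len(frames), len(ids), 3) coordinates in the co-rotating channel
    frame: columns are (x along e1, y along e2, z along the axis)."""
    out = np.empty((frames.size, ids.size, 3))
    for j, f in enumerate(frames):
        e1, e2, u = geom.basis(int(f))
        d = traj.positions[f, ids] - geom.origins[f]
        out[j] = d @ np.column_stack([e1, e2, u])
    return out


def _inside_coords(traj: Trajectory, res: ResidencyMatrix,
                   geom: ChannelGeometry, window_start: float) -> np.ndarray:
    frames = np.nonzero(traj.times >= window_start)[0]
    coords = _channel_frame_coords(traj, geom, res.particle_ids, frames)
    mask = res.inside[:, frames].T  # (n_frames_sel, n_tracked)
    pts = coords[mask]
    if pts.size == 0:
        raise ValueError("empty map: no inside counts in the window")
    return pts


def planar_heatmap(traj: Trajectory, res: ResidencyMatrix,
                   geom: ChannelGeometry, plane: str, bin_width: float = 0.25,
                   window_start: float = 0.0) -> DensityMap2D:
    """Positional probability heatmap in the XY, XZ or YZ channel plane."""
    if plane not in _PLANES:
        raise ValueError(f"plane must be one of {sorted(_PLANES)}")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pts = _inside_coords(traj, res, geom, window_start)
    i, j = _PLANES[plane]
    a, b = pts[:, i], pts[:, j]

    def edges(v: np.ndarray) -> np.ndarray:
        lo = np.floor(v.min() / bin_width) * bin_width
        n = max(1, int(np.ceil((v.max() - lo) / bin_width + 1e-9)))
        e = lo + bin_width * np.arange(n + 1)
        e[-1] = max(e[-1], v.max())
        return e

    counts, xe, ye = np.histogram2d(a, b, bins=[edges(a), edges(b)])
    return DensityMap2D(plane=plane, x_edges=xe, y_edges=ye,
                        probability=counts / counts.sum())


def cylindrical_heatmap(traj: Trajectory, res: ResidencyMatrix,
                        geom: ChannelGeometry, r_bins: int, theta_bins: int,
                        window_start: float = 0.0,
                        jacobian_correction: bool = False) -> DensityMap2D:
    """Positional probability on the (R, θ) grid.

    With ``jacobian_correction`` the count fractions are divided by the cell
    area R·dR·dθ and renormalized, giving a number-density-like map.
    """
    if r_bins < 1 or theta_bins < 1:
        raise ValueError("bin counts must be ≥ 1")
    pts = _inside_coords(traj, res, geom, window_start)
    R = np.hypot(pts[:, 0], pts[:, 1])
    theta = np.arctan2(pts[:, 1], pts[:, 0])
    theta = np.where(theta >= np.pi, theta - 2 * np.pi, theta)
    r_edges = np.linspace(0.0, max(float(R.max()), geom.pore_radius), r_bins + 1)
    theta_edges = np.linspace(-np.pi, np.pi, theta_bins + 1)
    counts, _, _ = np.histogram2d(R, theta, bins=[r_edges, theta_edges])
    prob = counts / counts.sum()
    if jacobian_correction:
        r_mid = 0.5 * (r_edges[:-1] + r_edges[1:])
        area = r_mid[:, None] * np.diff(r_edges)[:, None] * np.diff(theta_edges)[None, :]
        prob = prob / area
        prob = prob / prob.sum()
    return DensityMap2D(plane="R-theta", x_edges=r_edges, y_edges=theta_edges,
                        probability=prob)


def backbone_overlay(traj: Trajectory, geom: ChannelGeometry,
                     groups: dict[str, str], plane: str) -> dict[str, np.ndarray]:
    """Time-averaged backbone reference positions projected to a plane.

    ``groups`` maps an overlay label (e.g. ``alpha_carbons``,
    ``carbonyl_oxygens``) to a trajectory group name.  Averaging happens in
    the co-rotating channel frame, so atoms of a rigidly rotating ring stay
    put.  Returns label -> (group_size, 2) projected mean positions.
    """
    if plane not in _PLANES:
        raise ValueError(f"plane must be one of {sorted(_PLANES)}")
    i, j = _PLANES[plane]
    frames = np.arange(traj.n_frames)
    overlays: dict[str, np.ndarray] = {}
    for label, group_name in groups.items():
        ids = traj.group(group_name)
        if ids.size == 0:
            raise ConfigurationError(f"overlay group {group_name!r} is empty")
        coords = _channel_frame_coords(traj, geom, ids, frames)
        mean = coords.mean(axis=0)
        overlays[label] = mean[:, (i, j)]
    return overlays
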