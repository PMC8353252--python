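"""Pore residency: inside/outside classification, occupancy and z-traces.

A particle is inside the channel at a frame iff its radial distance from the
fitted axis is at most the pore radius and its axial coordinate lies within
the channel bounds.  The resulting boolean residency matrix is the substrate
for occupancy statistics, survival curves, per-particle z-traces and
z-presence histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import ChannelGeometry, ConfigurationError, Trajectory, to_cylindrical

__all__ = [
    "ResidencyMatrix",
    "OccupancySeries",
    "ZTraceSet",
    "classify_inside",
    "occupancy_stats",
    "z_traces",
]


@dataclass
class ResidencyMatrix:
    """Boolean inside/outside state per tracked particle per frame."""

    particle_ids: np.ndarray   # (n_tracked,) indices into the trajectory
    inside: np.ndarray         # (n_tracked, n_frames) bool
    times: np.ndarray          # (n_frames,) ps

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        self.particle_ids = np.asarray(self.particle_ids, dtype=np.intp)
        self.times = np.asarray(self.times, dtype=float)
        if self.inside.shape != (self.particle_ids.size, self.times.size):
            raise ValueError("inside must have shape (n_tracked, n_frames)")

    @property
    def n_tracked(self) -> int:
        return self.inside.shape[0]

    @property
    def n_frames(self) -> int:
        return self.inside.shape[1]

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def counts(self) -> np.ndarray:
        """Per-frame count of inside particles."""
        return self.inside.sum(axis=0)


@dataclass
class OccupancySeries:
    """Per-frame occupancy counts with windowed mean and SD."""

    times: np.ndarray
    counts: np.ndarray
    window: tuple[float, float]
    mean: float
    sd: float


@dataclass
class ZTraceSet:
    """Per-particle (time, z) traces while inside, plus z-presence histogram.

    ``presence`` counts, per z-bin, the number of frames in which at least
    one tracked particle was inside the pore within that bin.
    """

    traces: dict[int, np.ndarray]   # particle id -> (n_i, 2) [time_ps, z_A]
    bin_edges: np.ndarray
    presence: np.ndarray
    times: np.ndarray = field(repr=False, default=None)


def classify_inside(traj: Trajectory, geom: ChannelGeometry,
                    tracked_group: str) -> ResidencyMatrix:
    """Classify tracked particles as inside/outside the pore per frame.

    Inside at frame f iff R ≤ pore_radius and z_lo[f] ≤ z ≤ z_hi[f] in the
    channel frame of f.
    """
    ids = traj.group(tracked_group)
    if ids.size == 0:
        raise ConfigurationError(f"tracked group {tracked_group!r} is empty")
    n_frames = traj.n_frames
    inside = np.empty((ids.size, n_frames), dtype=bool)
    for f in range(n_frames):
        cyl = to_cylindrical(traj.positions[f, ids], geom, f)
        inside[:, f] = ((cyl.R <= geom.pore_radius)
                        & (cyl.z >= geom.z_lo[f])
                        & (cyl.z <= geom.z_hi[f]))
    return ResidencyMatrix(ids, inside, traj.times)


def occupancy_stats(res: ResidencyMatrix, window_start: float,
                    window_end: float) -> OccupancySeries:
    """Per-frame inside counts with mean/SD over [window_start, window_end] ps."""
    mask = (res.times >= window_start) & (res.times <= window_end)
    if not mask.any():
        raise ValueError(
            f"empty analysis window [{window_start}, {window_end}] ps"
        )
    counts = res.counts()
    sel = counts[mask]
    return OccupancySeries(
        times=res.times,
        counts=counts,
        window=(float(window_start), float(window_end)),
        mean=float(sel.mean()),
        sd=float(sel.std()),
    )


def z_traces(res: ResidencyMatrix, traj: Trajectory, geom: ChannelGeometry,
             bin_width: float = 0.5,
             bin_edges: np.ndarray | None = None) -> ZTraceSet:
    """Per-particle z-traces restricted to inside frames, and the z-presence
    histogram (frames with ≥ 1 inside particle per z-bin).

    The z grid spans the pore bounds with ``bin_width``-wide bins unless an
    explicit uniform ``bin_edges`` grid is given (e.g. to match another
    analysis' binning).
    """
    if bin_edges is not None:
        edges = np.asarray(bin_edges, dtype=float)
        widths = np.diff(edges)
        if widths.size == 0 or np.any(widths <= 0) or \
                not np.allclose(widths, widths[0]):
            raise ValueError("bin_edges must be a uniform increasing grid")
        bin_width = float(widths[0])
        z_min = float(edges[0])
        n_bins = widths.size
    else:
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        z_min = float(np.min(geom.z_lo))
        z_max = float(np.max(geom.z_hi))
        n_bins = max(1, int(np.ceil((z_max - z_min) / bin_width)))
        edges = z_min + bin_width * np.arange(n_bins + 1)

    n_frames = traj.n_frames
    z_all = np.empty((res.n_tracked, n_frames))
    for f in range(n_frames):
        cyl = to_cylindrical(traj.positions[f, res.particle_ids], geom, f)
        z_all[:, f] = cyl.z

    traces: dict[int, np.ndarray] = {}
    for i, pid in enumerate(res.particle_ids):
        m = res.inside[i]
        if m.any():
            traces[int(pid)] = np.column_stack([res.times[m], z_all[i, m]])

    presence = np.zeros(n_bins, dtype=np.intp)
    for f in range(n_frames):
        m = res.inside[:, f]
        if not m.any():
            continue
        idx = np.floor((z_all[m, f] - z_min) / bin_width).astype(np.intp)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        presence[np.unique(idx)] += 1

    return ZTraceSet(traces=traces, bin_edges=edges, presence=presence,
                     times=res.times)
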