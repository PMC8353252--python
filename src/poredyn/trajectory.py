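"""Trajectory containers, channel-axis fitting and cylindrical coordinates.

A :class:`Trajectory` is a light in-memory container: frames of particle
positions (Å) with times (ps), orthorhombic box lengths and named particle
groups.  Real MD formats (GRO/PDB topologies with XTC/TRR/DCD frames) are
read through MDAnalysis; a whitespace plain-text fixture dialect is read and
written natively so the full pipeline is testable without binary inputs.

The channel frame is defined per stored frame: the axis is the principal
axis of the backbone point cloud (sign-aligned across frames so it never
flips), the origin sits at the axial midpoint of the backbone, and the
angular reference co-rotates with a designated backbone subset so angular
density lobes stay registered even if the tube rotates in the laboratory
frame.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trajectory",
    "ChannelGeometry",
    "CylindricalCoords",
    "load_trajectory",
    "write_fixture",
    "read_fixture",
    "fit_channel_axis",
    "to_cylindrical",
    "from_cylindrical",
    "wrap_into_cell",
]


class ConfigurationError(ValueError):
    """A group definition or configuration entry does not resolve."""


@dataclass
class Trajectory:
    """Ordered frames of particle positions with named particle groups.

    Attributes
    ----------
    positions : (n_frames, n_particles, 3) float array, Å
    times : (n_frames,) float array, ps, strictly increasing, constant step
    boxes : (n_frames, 3) float array, orthorhombic box lengths, Å
    groups : mapping group name -> integer index array
    """

    positions: np.ndarray
    times: np.ndarray
    boxes: np.ndarray
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_particles, 3)")
        if self.times.shape != (self.n_frames,):
            raise ValueError("times length must match n_frames")
        if self.boxes.shape != (self.n_frames, 3):
            raise ValueError("boxes must have shape (n_frames, 3)")
        if np.any(self.boxes <= 0):
            raise ValueError("box lengths must be positive")
        if self.n_frames > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("frame times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("non-constant frame spacing")
        self.groups = {
            name: np.asarray(idx, dtype=np.intp) for name, idx in self.groups.items()
        }
        for name, idx in self.groups.items():
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_particles):
                raise ConfigurationError(
                    f"group {name!r} has indices outside [0, {self.n_particles})"
                )

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def dt_saved(self) -> float:
        """Time between stored frames (ps)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def group(self, name: str) -> np.ndarray:
        try:
            return self.groups[name]
        except KeyError:
            raise ConfigurationError(f"undefined group {name!r}") from None

    def group_positions(self, name: str) -> np.ndarray:
        """Positions of a named group, shape (n_frames, group_size, 3)."""
        return self.positions[:, self.group(name), :]


@dataclass
class ChannelGeometry:
    """Per-frame channel frame: axis, angular reference, bounds and radius.

    ``origins[f]`` lies on the axis at the axial midpoint of the backbone, so
    the axial coordinate ``z`` of :func:`to_cylindrical` is already centred.
    ``z_lo``/``z_hi`` are per-frame axial bounds of the pore (midpoint-
    relative, Å); ``refs[f]`` is the in-plane unit vector defining θ = 0.
    """

    origins: np.ndarray      # (n_frames, 3)
    directions: np.ndarray   # (n_frames, 3), unit vectors
    refs: np.ndarray         # (n_frames, 3), unit vectors ⟂ directions
    z_lo: np.ndarray         # (n_frames,)
    z_hi: np.ndarray         # (n_frames,)
    pore_radius: float

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("axis directions must be unit vectors")
        if np.any(self.z_lo >= self.z_hi):
            raise ValueError("z_lo must be < z_hi")
        if self.pore_radius <= 0:
            raise ValueError("pore_radius must be positive")

    @property
    def n_frames(self) -> int:
        return self.origins.shape[0]

    def basis(self, frame: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (e1, e2, u) channel basis at a frame; θ from e1 to e2."""
        u = self.directions[frame]
        e1 = self.refs[frame]
        e2 = np.cross(u, e1)
        return e1, e2, u


@dataclass
class CylindricalCoords:
    """Channel-centred cylindrical coordinates.

    R ≥ 0 (Å), theta in [−π, π) (rad), z midpoint-centred axial coordinate (Å).
    """

    R: np.ndarray
    theta: np.ndarray
    z: np.ndarray


# ---------------------------------------------------------------------------
# fixture dialect I/O
# ---------------------------------------------------------------------------

def write_fixture(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write a trajectory in the plain-text fixture dialect.

    Format: one header line ``n_frames n_particles dt_saved box_x box_y box_z``
    followed by ``n_frames`` blocks of ``n_particles`` lines ``x y z`` (Å).
    The box is constant across frames in this dialect.
    """
    with open(path, "w") as fh:
        b = [float(v) for v in traj.boxes[0]]
        fh.write(
            f"{traj.n_frames} {traj.n_particles} {float(traj.dt_saved)!r} "
            f"{b[0]!r} {b[1]!r} {b[2]!r}\n"
        )
        for f in range(traj.n_frames):
            for p in range(traj.n_particles):
                x, y, z = (float(v) for v in traj.positions[f, p])
                fh.write(f"{x!r} {y!r} {z!r}\n")


def read_fixture(path: str | os.PathLike,
                 groups: dict[str, list[int]] | None = None) -> Trajectory:
    """Read the plain-text fixture dialect written by :func:`write_fixture`."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"fixture trajectory not found: {path}")
    with open(path) as fh:
        header = fh.readline().split()
        n_frames, n_particles = int(header[0]), int(header[1])
        dt_saved = float(header[2])
        box = np.array([float(v) for v in header[3:6]])
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    expected = n_frames * n_particles
    if data.shape != (expected, 3):
        raise ValueError(
            f"fixture body has shape {data.shape}, expected ({expected}, 3)"
        )
    positions = data.reshape(n_frames, n_particles, 3)
    times = np.arange(n_frames) * (dt_saved if dt_saved > 0 else 1.0)
    boxes = np.tile(box, (n_frames, 1))
    return Trajectory(positions, times, boxes, groups=dict(groups or {}))


def _resolve_groups(universe, group_defs: dict) -> dict[str, np.ndarray]:
    groups: dict[str, np.ndarray] = {}
    for name, sel in group_defs.items():
        if isinstance(sel, str):
            ag = universe.select_atoms(sel)
            idx = np.asarray(ag.ix, dtype=np.intp)
        else:
            idx = np.asarray(list(sel), dtype=np.intp)
        if idx.size == 0:
            raise ConfigurationError(f"group {name!r} selects no particles")
        groups[name] = idx
    return groups


def load_trajectory(topology_path: str | os.PathLike,
                    trajectory_path: str | os.PathLike | None = None,
                    group_defs: dict | None = None) -> Trajectory:
    """Load a trajectory with named particle groups.

    GRO/PDB topologies (optionally with XTC/TRR/DCD frames) are read through
    MDAnalysis and reported in Å.  Any other extension is treated as the
    plain-text fixture dialect (``trajectory_path`` ignored).  ``group_defs``
    maps group names to explicit index lists, or — on the MDAnalysis path —
    selection strings.
    """
    topology_path = os.fspath(topology_path)
    if not os.path.exists(topology_path):
        raise FileNotFoundError(f"topology not found: {topology_path}")
    ext = os.path.splitext(topology_path)[1].lower()
    group_defs = group_defs or {}

    if ext not in {".gro", ".pdb"}:
        idx_groups = {}
        for name, sel in group_defs.items():
            if isinstance(sel, str):
                raise ConfigurationError(
                    f"group {name!r}: selection strings need a GRO/PDB topology"
                )
            if len(sel) == 0:
                raise ConfigurationError(f"group {name!r} selects no particles")
            idx_groups[name] = list(sel)
        return read_fixture(topology_path, groups=idx_groups)

    import MDAnalysis as mda

    if trajectory_path is not None:
        trajectory_path = os.fspath(trajectory_path)
        if not os.path.exists(trajectory_path):
            raise FileNotFoundError(f"trajectory not found: {trajectory_path}")
        u = mda.Universe(topology_path, trajectory_path)
    else:
        u = mda.Universe(topology_path)

    groups = _resolve_groups(u, group_defs)
    n_frames = len(u.trajectory)
    n_particles = len(u.atoms)
    positions = np.empty((n_frames, n_particles, 3))
    times = np.empty(n_frames)
    boxes = np.empty((n_frames, 3))
    for i, ts in enumerate(u.trajectory):
        positions[i] = u.atoms.positions
        times[i] = ts.time
        boxes[i] = ts.dimensions[:3]
    if n_frames > 1 and np.allclose(np.diff(times), 0):
        times = np.arange(n_frames, dtype=float)
    return Trajectory(positions, times, boxes, groups=groups)


# ---------------------------------------------------------------------------
# channel frame
# ---------------------------------------------------------------------------

def fit_channel_axis(traj: Trajectory, backbone_group: str,
                     pore_radius: float, z_pad: float = 0.0,
                     reference_group: str | None = None,
                     lab_axis: np.ndarray | None = None) -> ChannelGeometry:
    """Fit the channel axis per frame from a backbone particle group.

    The axis is the largest-variance eigendirection of the centred backbone
    second-moment tensor, sign-aligned frame-to-frame.  The origin is placed
    at the axial midpoint of the backbone projection; ``z_lo``/``z_hi`` are
    the backbone axial extent ± ``z_pad``.  The θ = 0 reference co-rotates
    with ``reference_group`` (default: the first backbone particle).  Passing
    ``lab_axis`` skips the fit and uses a laboratory-fixed axis instead.
    """
    bb = traj.group_positions(backbone_group)
    if bb.shape[1] < 3:
        raise ConfigurationError("backbone group needs at least 3 particles")
    n_frames = traj.n_frames
    ref_idx = (traj.group(reference_group) if reference_group is not None
               else traj.group(backbone_group)[:1])

    origins = np.empty((n_frames, 3))
    directions = np.empty((n_frames, 3))
    refs = np.empty((n_frames, 3))
    z_lo = np.empty(n_frames)
    z_hi = np.empty(n_frames)

    prev_u = None
    for f in range(n_frames):
        pts = bb[f]
        centroid = pts.mean(axis=0)
        centered = pts - centroid
        if lab_axis is not None:
            u = np.asarray(lab_axis, dtype=float)
            u = u / np.linalg.norm(u)
        else:
            cov = centered.T @ centered
            if np.allclose(cov, 0, atol=1e-12):
                raise np.linalg.LinAlgError(
                    "degenerate backbone point cloud (all points coincident)"
                )
            w, v = np.linalg.eigh(cov)
            u = v[:, -1]
        if prev_u is not None and np.dot(u, prev_u) < 0:
            u = -u
        elif prev_u is None and u[2] < 0:
            u = -u  # deterministic first-frame orientation
        prev_u = u

        s = centered @ u
        mid = 0.5 * (s.min() + s.max())
        half = 0.5 * (s.max() - s.min())
        origins[f] = centroid + mid * u
        directions[f] = u
        z_lo[f] = -(half + z_pad)
        z_hi[f] = half + z_pad

        ref_pt = traj.positions[f, ref_idx].mean(axis=0)
        d = ref_pt - origins[f]
        perp = d - np.dot(d, u) * u
        norm = np.linalg.norm(perp)
        if norm < 1e-12:
            # reference on axis: fall back to any transverse direction
            trial = np.array([1.0, 0.0, 0.0])
            perp = trial - np.dot(trial, u) * u
            norm = np.linalg.norm(perp)
            if norm < 1e-12:
                perp = np.array([0.0, 1.0, 0.0]) - u[1] * u
                norm = np.linalg.norm(perp)
        refs[f] = perp / norm

    return ChannelGeometry(origins, directions, refs, z_lo, z_hi,
                           float(pore_radius))


def to_cylindrical(positions: np.ndarray, geom: ChannelGeometry,
                   frame: int) -> CylindricalCoords:
    """Convert Cartesian points (Å) to channel-centred cylindrical coordinates.

    θ is measured from the co-rotating reference direction; a point on the
    axis gets θ = 0 by convention.  z is the signed axial projection relative
    to the channel midpoint.
    """
    if not (0 <= frame < geom.n_frames):
        raise IndexError(f"frame {frame} outside geometry range")
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    e1, e2, u = geom.basis(frame)
    d = pts - geom.origins[frame]
    z = d @ u
    x = d @ e1
    y = d @ e2
    R = np.hypot(x, y)
    theta = np.where(R > 1e-9, np.arctan2(y, x), 0.0)
    # arctan2 returns (−π, π]; fold +π onto −π for the [−π, π) contract
    theta = np.where(theta >= np.pi, theta - 2 * np.pi, theta)
    squeeze = np.asarray(positions).ndim == 1
    if squeeze:
        return CylindricalCoords(R[0], theta[0], z[0])
    return CylindricalCoords(R, theta, z)


def from_cylindrical(coords: CylindricalCoords, geom: ChannelGeometry,
                     frame: int) -> np.ndarray:
    """Inverse of :func:`to_cylindrical` (Cartesian laboratory coordinates)."""
    e1, e2, u = geom.basis(frame)
    R = np.atleast_1d(coords.R)
    theta = np.atleast_1d(coords.theta)
    z = np.atleast_1d(coords.z)
    pts = (geom.origins[frame]
           + np.outer(R * np.cos(theta), e1)
           + np.outer(R * np.sin(theta), e2)
           + np.outer(z, u))
    return pts[0] if np.isscalar(coords.R) or np.ndim(coords.R) == 0 else pts


def wrap_into_cell(traj: Trajectory) -> Trajectory:
    """Map every coordinate into [0, L) per dimension (orthorhombic box)."""
    if np.any(traj.boxes <= 0):
        raise ValueError("box lengths must be positive")
    wrapped = np.mod(traj.positions, traj.boxes[:, None, :])
    return Trajectory(wrapped, traj.times.copy(), traj.boxes.copy(),
                      groups={k: v.copy() for k, v in traj.groups.items()})


def unwrap_positions(traj: Trajectory) -> np.ndarray:
    """Remove periodic jumps by accumulating minimum-image displacements.

    Returns an (n_frames, n_particles, 3) array continuous in time; frame 0
    equals the stored frame 0.  Assumes no particle moves more than half a
    box length between stored frames.
    """
    pos = traj.positions
    out = np.empty_like(pos)
    out[0] = pos[0]
    for f in range(1, traj.n_frames):
        box = traj.boxes[f]
        delta = pos[f] - pos[f - 1]
        delta -= box * np.round(delta / box)
        out[f] = out[f - 1] + delta
    return out
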