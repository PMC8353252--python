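"""Decomposed radial distribution functions, coordination numbers and
geometric hydrogen-bond counting.

RDFs are computed per contributor species around inside centers (e.g. a
cation inside the pore), with minimum-image distances and the normalization

    g_c(r) = <pair counts in [r, r+dr)> / (n_centers · n_contributors_c
                                           · shell_volume / box_volume)

averaged over window frames with at least one inside center, which recovers
g → 1 in the ideal-gas limit.  The first coordination shell radius is the
first local minimum of a lightly smoothed g(r) after the first peak above 1.
Coordination numbers count contributors within that radius per (frame,
center) observation and are reported as mean ± SD.  H-bonds use the common
geometric criterion: donor–acceptor distance ≤ cutoff and donor–hydrogen–
acceptor angle ≥ angle cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .occupancy import ResidencyMatrix
from .trajectory import Trajectory

__all__ = [
    "RDFProfile",
    "CoordinationTable",
    "HBondCriteria",
    "rdf_decomposed",
    "first_shell_radius",
    "coordination_numbers",
    "count_hbonds",
    "theoretical_max_hbonds",
]


@dataclass
class RDFProfile:
    """g(r) per contributor species with full normalization metadata."""

    r: np.ndarray                          # bin centers (Å)
    g: dict[str, np.ndarray]               # contributor -> g(r)
    dr: float
    n_centers: float                       # mean inside centers per frame
    n_contributors: dict[str, int]
    n_frames: int
    box_volume: float
    raw_counts: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class CoordinationTable:
    """Mean ± SD first-shell contacts per contributor species."""

    mean: dict[str, float]
    sd: dict[str, float]
    shell_radius: dict[str, float]
    n_observations: int


@dataclass
class HBondCriteria:
    """Geometric H-bond criteria: D···A distance (Å) and D–H···A angle (deg)."""

    distance_cutoff: float = 3.5
    angle_cutoff: float = 150.0

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.angle_cutoff > 180:
            raise ValueError("angle cutoff must be ≤ 180 degrees")


def _minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def rdf_decomposed(traj: Trajectory, res: ResidencyMatrix, centers: str,
                   contributors: list[str], r_max: float, dr: float,
                   window_start: float = 0.0) -> RDFProfile:
    """Contribution-decomposed g(r) around inside centers.

    ``res`` must be the residency matrix of the ``centers`` group; frames in
    the window with no inside center are skipped.
    """
    if not (r_max > dr > 0):
        raise ValueError("need r_max > dr > 0")
    center_ids = traj.group(centers)
    if not np.array_equal(np.sort(center_ids), np.sort(res.particle_ids)):
        raise ValueError("residency matrix does not track the centers group")
    order = {pid: i for i, pid in enumerate(res.particle_ids)}
    row = np.array([order[p] for p in center_ids], dtype=np.intp)

    n_bins = int(round(r_max / dr))
    edges = dr * np.arange(n_bins + 1)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)

    frames = np.nonzero(traj.times >= window_start)[0]
    counts = {c: np.zeros(n_bins) for c in contributors}
    contrib_ids = {c: traj.group(c) for c in contributors}
    n_frames_used = 0
    total_centers = 0
    box_volume = float(np.prod(traj.boxes[0]))

    for f in frames:
        inside = res.inside[row, f]
        if not inside.any():
            continue
        n_frames_used += 1
        c_pos = traj.positions[f, center_ids[inside]]
        total_centers += c_pos.shape[0]
        box = traj.boxes[f]
        for c in contributors:
            p = traj.positions[f, contrib_ids[c]]
            delta = p[None, :, :] - c_pos[:, None, :]
            dist = np.linalg.norm(_minimum_image(delta, box), axis=2).ravel()
            h, _ = np.histogram(dist, bins=edges)
            counts[c] += h

    if n_frames_used == 0:
        raise ValueError("no inside centers in the analysis window")

    mean_centers = total_centers / n_frames_used
    g: dict[str, np.ndarray] = {}
    for c in contributors:
        n_c = contrib_ids[c].size
        ideal = mean_centers * n_c * shell_vol / box_volume
        g[c] = counts[c] / n_frames_used / ideal

    r_mid = 0.5 * (edges[:-1] + edges[1:])
    return RDFProfile(r=r_mid, g=g, dr=dr, n_centers=mean_centers,
                      n_contributors={c: int(contrib_ids[c].size)
                                      for c in contributors},
                      n_frames=n_frames_used, box_volume=box_volume,
                      raw_counts={c: counts[c] / n_frames_used
                                  for c in contributors})


def first_shell_radius(profile: RDFProfile, contributor: str,
                       smooth_width: int = 3) -> float:
    """First-shell radius: first local minimum of smoothed g(r) after the
    first peak exceeding 1."""
    g = profile.g[contributor]
    if smooth_width > 1:
        kernel = np.ones(smooth_width) / smooth_width
        g = np.convolve(g, kernel, mode="same")
    r = profile.r

    peak = None
    for i in range(1, g.size - 1):
        if g[i] > 1.0 and g[i] >= g[i - 1] and g[i] >= g[i + 1]:
            peak = i
            break
    if peak is None:
        raise ValueError(f"no first shell: no g(r) peak above 1 for "
                         f"{contributor!r}")
    for i in range(peak + 1, g.size - 1):
        if g[i] <= g[i - 1] and g[i] <= g[i + 1]:
            return float(r[i])
    raise ValueError(f"no first shell: no minimum after the first peak for "
                     f"{contributor!r}")


def coordination_numbers(traj: Trajectory, res: ResidencyMatrix, centers: str,
                         contributors: list[str],
                         shell_radius: dict[str, float],
                         window_start: float = 0.0) -> CoordinationTable:
    """Mean ± SD contributor contacts within the first shell of inside
    centers, over all (frame, center) observations in the window."""
    for c in contributors:
        if shell_radius[c] <= 0:
            raise ValueError(f"shell radius for {c!r} must be positive")
    center_ids = traj.group(centers)
    order = {pid: i for i, pid in enumerate(res.particle_ids)}
    row = np.array([order[p] for p in center_ids], dtype=np.intp)
    contrib_ids = {c: traj.group(c) for c in contributors}

    frames = np.nonzero(traj.times >= window_start)[0]
    per_obs: dict[str, list[np.ndarray]] = {c: [] for c in contributors}
    n_obs = 0
    for f in frames:
        inside = res.inside[row, f]
        if not inside.any():
            continue
        c_pos = traj.positions[f, center_ids[inside]]
        n_obs += c_pos.shape[0]
        box = traj.boxes[f]
        for c in contributors:
            p = traj.positions[f, contrib_ids[c]]
            delta = p[None, :, :] - c_pos[:, None, :]
            dist = np.linalg.norm(_minimum_image(delta, box), axis=2)
            per_obs[c].append((dist <= shell_radius[c]).sum(axis=1))
    if n_obs == 0:
        raise ValueError("no inside centers in the analysis window")

    mean = {}
    sd = {}
    for c in contributors:
        obs = np.concatenate(per_obs[c]).astype(float)
        mean[c] = float(obs.mean())
        sd[c] = float(obs.std())
    return CoordinationTable(mean=mean, sd=sd,
                             shell_radius={c: float(shell_radius[c])
                                           for c in contributors},
                             n_observations=n_obs)


def coordination_from_rdf(profile: RDFProfile, contributor: str,
                          shell_radius: float) -> float:
    """Coordination number by integrating the RDF: 4πρ∫₀^rc g(r) r² dr.

    Evaluated on the RDF's own shell discretization (sum of g · ideal shell
    population over bins up to the shell radius), which is the exact inverse
    of the RDF normalization and serves as an independent cross-check of
    direct neighbor counting.
    """
    edges = np.concatenate([[profile.r[0] - profile.dr / 2],
                            profile.r + profile.dr / 2])
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho = profile.n_contributors[contributor] / profile.box_volume
    mask = edges[1:] <= shell_radius + 1e-9
    return float(np.sum(profile.g[contributor][mask] * rho * shell_vol[mask]))


def count_hbonds(positions: np.ndarray, donors: list[tuple[int, int]],
                 acceptors: list[int],
                 criteria: HBondCriteria | None = None,
                 labels: dict[tuple[int, int], str] | None = None
                 ) -> tuple[int, list[tuple[int, int, int]]]:
    """Count geometric hydrogen bonds in one frame.

    ``donors`` are (donor heavy atom, attached hydrogen) index pairs;
    ``acceptors`` are acceptor atom indices.  A bond exists when the D···A
    distance is at most the cutoff and the D–H···A angle is at least the
    angle cutoff.  Returns the count and the (D, H, A) index triplets;
    ``labels`` optionally maps (D, A) pairs to classification strings and is
    echoed on the triplets when provided.
    """
    criteria = criteria or HBondCriteria()
    pos = np.asarray(positions, dtype=float)
    bonds: list[tuple[int, int, int]] = []
    cos_cut = np.cos(np.deg2rad(criteria.angle_cutoff))
    for d, h in donors:
        if d < 0 or h < 0 or d >= len(pos) or h >= len(pos):
            raise ValueError(f"malformed donor pair ({d}, {h})")
        for a in acceptors:
            if a == d or a == h:
                continue
            da = pos[a] - pos[d]
            r_da = np.linalg.norm(da)
            if r_da > criteria.distance_cutoff:
                continue
            hd = pos[d] - pos[h]
            ha = pos[a] - pos[h]
            denom = np.linalg.norm(hd) * np.linalg.norm(ha)
            if denom == 0:
                continue
            # D–H···A angle at the hydrogen; 180° = linear bond
            cos_ang = np.dot(hd, ha) / denom
            if cos_ang <= cos_cut:
                bonds.append((d, h, a))
    return len(bonds), bonds


def theoretical_max_hbonds(n_rings: int, bonds_per_interface: int) -> int:
    """Theoretical maximum inter-ring backbone H-bonds in a stacked-ring
    nanotube: one interface per adjacent ring pair, each saturated.

    For a tube of 8 stacked cyclic peptides with 12 bonds per interface this
    gives (8 − 1) · 12 = 84.
    """
    if n_rings < 1:
        raise ValueError("n_rings must be ≥ 1")
    if bonds_per_interface < 0:
        raise ValueError("bonds_per_interface must be ≥ 0")
    return (n_rings - 1) * bonds_per_interface
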