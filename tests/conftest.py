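"""Shared fixtures: small hand-built trajectories and geometries."""

import numpy as np
import pytest

from poredyn import (ChannelGeometry, ResidencyMatrix, Trajectory,
                     fit_channel_axis)


def make_ring_stack(n_rings=8, atoms_per_ring=12, radius=9.0, spacing=4.9,
                    center=(20.0, 20.0, 20.0)):
    """Static stack of rings along laboratory z, centred at ``center``."""
    center = np.asarray(center)
    z = (np.arange(n_rings) - (n_rings - 1) / 2) * spacing
    a = 2 * np.pi * np.arange(atoms_per_ring) / atoms_per_ring
    pts = np.array([[radius * np.cos(t), radius * np.sin(t), zz]
                    for zz in z for t in a])
    return pts + center


def make_static_trajectory(extra_particles, n_frames=3, dt=1.0, box=40.0,
                           **ring_kwargs):
    """Trajectory of a static ring stack plus given mobile particle positions.

    ``extra_particles``: (n_extra, 3) constant positions, or
    (n_frames, n_extra, 3) per-frame positions.  Groups: 'backbone' for the
    stack, 'mobile' for the extras.
    """
    bb = make_ring_stack(**ring_kwargs)
    extra = np.asarray(extra_particles, dtype=float)
    if extra.ndim == 2:
        extra = np.tile(extra, (n_frames, 1, 1))
    n_frames = extra.shape[0]
    frames = np.concatenate([extra, np.tile(bb, (n_frames, 1, 1))], axis=1)
    n_extra = extra.shape[1]
    return Trajectory(
        frames, dt * np.arange(n_frames),
        np.tile([box, box, box], (n_frames, 1)),
        groups={"mobile": np.arange(n_extra),
                "backbone": n_extra + np.arange(len(bb))})


@pytest.fixture
def ring_trajectory():
    """3-frame static ring-stack trajectory with one centred mobile particle."""
    return make_static_trajectory([[20.0, 20.0, 20.0]])


@pytest.fixture
def ring_geometry(ring_trajectory):
    return fit_channel_axis(ring_trajectory, "backbone", pore_radius=9.0,
                            z_pad=1.0)


def residency_from_flags(flags, dt=1.0):
    flags = np.asarray(flags, dtype=bool)
    return ResidencyMatrix(np.arange(flags.shape[0]), flags,
                           dt * np.arange(flags.shape[1]))
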