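"""Trajectory loading, channel-axis fitting and cylindrical coordinates."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from poredyn import (ConfigurationError, Trajectory, fit_channel_axis,
                     from_cylindrical, load_trajectory, read_fixture,
                     to_cylindrical, wrap_into_cell, write_fixture)
from poredyn.trajectory import unwrap_positions

from conftest import make_ring_stack, make_static_trajectory


def write_tiny_fixture(path):
    """3 frames, 2 particles, dt 1 ps, 10 Å cubic box."""
    lines = ["3 2 1.0 10.0 10.0 10.0"]
    for f in range(3):
        lines.append(f"{1.0 + f} 2.0 3.0")
        lines.append(f"4.0 {5.0 + f} 6.0")
    path.write_text("\n".join(lines) + "\n")


class TestFixtureDialect:
    def test_load_with_groups(self, tmp_path):
        path = tmp_path / "traj.txt"
        write_tiny_fixture(path)
        traj = load_trajectory(path, group_defs={"water": [0], "ion": [1]})
        assert traj.n_frames == 3
        assert traj.n_particles == 2
        assert traj.group("water").size == 1
        assert traj.group("ion").size == 1
        assert traj.positions[2, 0, 0] == pytest.approx(3.0)
        assert traj.dt_saved == pytest.approx(1.0)

    def test_out_of_range_group_is_configuration_error(self, tmp_path):
        path = tmp_path / "traj.txt"
        write_tiny_fixture(path)
        with pytest.raises(ConfigurationError, match="bad"):
            load_trajectory(path, group_defs={"bad": [99]})

    def test_missing_file_names_path(self):
        with pytest.raises(FileNotFoundError, match="nope.txt"):
            load_trajectory("nope.txt")

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        traj = Trajectory(rng.uniform(0, 30, (4, 7, 3)), np.arange(4) * 2.0,
                          np.tile([30.0, 30.0, 30.0], (4, 1)),
                          groups={"all": np.arange(7)})
        path = tmp_path / "rt.txt"
        write_fixture(traj, path)
        back = read_fixture(path, groups={"all": list(range(7))})
        np.testing.assert_allclose(back.positions, traj.positions, atol=1e-4)
        assert back.dt_saved == pytest.approx(2.0)

    def test_non_constant_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            Trajectory(np.zeros((3, 1, 3)), [0.0, 1.0, 3.0],
                       np.ones((3, 3)))


class TestGroPath:
    def test_gro_loads_in_angstrom(self, tmp_path):
        gro = tmp_path / "two.gro"
        gro.write_text(
            "two atoms\n 2\n"
            "    1SOL     OW    1   0.100   0.200   0.300\n"
            "    2NA      NA    2   0.400   0.500   0.600\n"
            "   2.00000   2.00000   2.00000\n")
        traj = load_trajectory(gro, group_defs={"ow": "name OW"})
        assert traj.n_particles == 2
        # GRO is in nm; the container contract is Å
        np.testing.assert_allclose(traj.positions[0, 0], [1.0, 2.0, 3.0],
                                   atol=1e-3)
        np.testing.assert_allclose(traj.boxes[0], [20.0, 20.0, 20.0],
                                   atol=1e-3)
        assert traj.group("ow").tolist() == [0]

    def test_empty_selection_is_configuration_error(self, tmp_path):
        gro = tmp_path / "two.gro"
        gro.write_text(
            "two atoms\n 2\n"
            "    1SOL     OW    1   0.100   0.200   0.300\n"
            "    2NA      NA    2   0.400   0.500   0.600\n"
            "   2.00000   2.00000   2.00000\n")
        with pytest.raises(ConfigurationError, match="ghost"):
            load_trajectory(gro, group_defs={"ghost": "name XX"})


class TestAxisFit:
    def test_stack_along_z(self):
        traj = make_static_trajectory(np.empty((0, 3)).reshape(0, 3))
        geom = fit_channel_axis(traj, "backbone", pore_radius=9.0)
        np.testing.assert_allclose(np.abs(geom.directions[0]), [0, 0, 1],
                                   atol=1e-9)
        np.testing.assert_allclose(geom.origins[0], [20, 20, 20], atol=1e-9)

    def test_rotated_stack_recovers_rotated_axis(self):
        rot = Rotation.from_rotvec([0.4, -0.3, 0.2]).as_matrix()
        bb = make_ring_stack(center=(0, 0, 0)) @ rot.T
        traj = Trajectory(bb[None], [0.0], [[99, 99, 99]],
                          groups={"backbone": np.arange(len(bb))})
        geom = fit_channel_axis(traj, "backbone", pore_radius=9.0)
        expected = rot @ np.array([0, 0, 1.0])
        angle = np.arccos(np.clip(abs(geom.directions[0] @ expected), 0, 1))
        assert angle < 1e-6

    def test_sign_continuity_across_frames(self):
        # jitter frames so the raw eigenvector sign is arbitrary per frame
        rng = np.random.default_rng(5)
        bb = make_ring_stack(center=(0, 0, 0))
        frames = np.array([bb + 0.01 * rng.standard_normal(bb.shape)
                           for _ in range(6)])
        traj = Trajectory(frames, np.arange(6.0),
                          np.tile([99.0, 99, 99], (6, 1)),
                          groups={"backbone": np.arange(len(bb))})
        geom = fit_channel_axis(traj, "backbone", pore_radius=9.0)
        dots = np.einsum("ij,ij->i", geom.directions[:-1],
                         geom.directions[1:])
        assert (dots > 0).all()

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(17)
        bb = make_ring_stack(center=(0, 0, 0))
        bb += 0.05 * rng.standard_normal(bb.shape)
        rot = Rotation.random(random_state=3).as_matrix()
        t1 = Trajectory(bb[None], [0.0], [[99, 99, 99]],
                        groups={"backbone": np.arange(len(bb))})
        t2 = Trajectory((bb @ rot.T)[None], [0.0], [[99, 99, 99]],
                        groups={"backbone": np.arange(len(bb))})
        g1 = fit_channel_axis(t1, "backbone", pore_radius=9.0)
        g2 = fit_channel_axis(t2, "backbone", pore_radius=9.0)
        assert abs(abs((rot @ g1.directions[0]) @ g2.directions[0]) - 1) < 1e-6

    def test_coincident_points_degenerate(self):
        bb = np.zeros((12, 3))
        traj = Trajectory(bb[None], [0.0], [[99, 99, 99]],
                          groups={"backbone": np.arange(12)})
        with pytest.raises(np.linalg.LinAlgError):
            fit_channel_axis(traj, "backbone", pore_radius=9.0)


class TestCylindrical:
    def test_basic_point(self, ring_trajectory, ring_geometry):
        # θ reference is the first backbone atom, at lab +x from the axis
        c = to_cylindrical(np.array([23.0, 20.0, 25.0]), ring_geometry, 0)
        assert c.R == pytest.approx(3.0)
        assert c.theta == pytest.approx(0.0)
        assert c.z == pytest.approx(5.0)

    def test_on_axis_convention(self, ring_geometry):
        c = to_cylindrical(np.array([20.0, 20.0, 27.0]), ring_geometry, 0)
        assert c.R == pytest.approx(0.0)
        assert c.theta == 0.0
        assert c.z == pytest.approx(7.0)

    def test_round_trip_identity(self, ring_geometry):
        rng = np.random.default_rng(23)
        pts = rng.uniform(5, 35, (50, 3))
        cyl = to_cylindrical(pts, ring_geometry, 1)
        back = from_cylindrical(cyl, ring_geometry, 1)
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_theta_range(self, ring_geometry):
        rng = np.random.default_rng(29)
        cyl = to_cylindrical(rng.uniform(0, 40, (200, 3)), ring_geometry, 0)
        assert (cyl.theta >= -np.pi).all() and (cyl.theta < np.pi).all()
        assert (cyl.R >= 0).all()


class TestWrap:
    def make(self, positions, box=10.0):
        pos = np.asarray(positions, float)[None]
        return Trajectory(pos, [0.0], [[box, box, box]])

    def test_examples(self):
        t = self.make([[12.0, -0.5, 3.0]])
        w = wrap_into_cell(t)
        np.testing.assert_allclose(w.positions[0, 0], [2.0, 9.5, 3.0])

    def test_idempotent(self):
        rng = np.random.default_rng(31)
        t = self.make(rng.uniform(-30, 30, (40, 3)))
        once = wrap_into_cell(t)
        twice = wrap_into_cell(once)
        np.testing.assert_allclose(twice.positions, once.positions)

    def test_preserves_minimum_image_distances(self):
        rng = np.random.default_rng(37)
        t = self.make(rng.uniform(-30, 30, (20, 3)))
        w = wrap_into_cell(t)
        box = np.array([10.0, 10.0, 10.0])

        def mi_dist(pos):
            d = pos[:, None, :] - pos[None, :, :]
            d -= box * np.round(d / box)
            return np.linalg.norm(d, axis=2)

        np.testing.assert_allclose(mi_dist(w.positions[0]),
                                   mi_dist(t.positions[0]), atol=1e-9)

    def test_zero_box_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(np.zeros((1, 1, 3)), [0.0], [[0.0, 10.0, 10.0]])


def test_unwrap_recovers_linear_motion():
    """A particle drifting at constant velocity through periodic walls has a
    continuous unwrapped track."""
    box = 10.0
    t = np.arange(30.0)
    true = np.column_stack([1.0 + 0.7 * t, np.full(30, 5.0), np.full(30, 5.0)])
    wrapped = true % box
    traj = Trajectory(wrapped[:, None, :], t, np.tile([box] * 3, (30, 1)))
    unwrapped = unwrap_positions(traj)
    np.testing.assert_allclose(unwrapped[:, 0, :] - unwrapped[0, 0, :],
                               true - true[0], atol=1e-9)
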