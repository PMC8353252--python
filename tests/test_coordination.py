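"""RDF decomposition, coordination numbers and H-bond counting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from poredyn import (HBondCriteria, Trajectory, count_hbonds,
                     coordination_numbers, first_shell_radius, rdf_decomposed,
                     theoretical_max_hbonds)
from poredyn.coordination import RDFProfile, coordination_from_rdf
from poredyn.occupancy import ResidencyMatrix


def ideal_gas_fixture(n_contrib=3000, n_frames=20, box=40.0, seed=139):
    """One fixed center at the box centre plus uniform contributors."""
    rng = np.random.default_rng(seed)
    pos = np.empty((n_frames, n_contrib + 1, 3))
    pos[:, 0, :] = box / 2
    pos[:, 1:, :] = rng.uniform(0, box, (n_frames, n_contrib, 3))
    traj = Trajectory(pos, np.arange(float(n_frames)),
                      np.tile([box] * 3, (n_frames, 1)),
                      groups={"center": [0],
                              "gas": 1 + np.arange(n_contrib)})
    res = ResidencyMatrix(np.array([0]), np.ones((1, n_frames), bool),
                          traj.times)
    return traj, res


class TestRDF:
    def test_ideal_gas_limit(self):
        """g(r) = 1 within 3/√counts for every shell in [3, 8] Å."""
        traj, res = ideal_gas_fixture()
        prof = rdf_decomposed(traj, res, "center", ["gas"], r_max=9.0,
                              dr=0.25)
        sel = (prof.r >= 3.0) & (prof.r <= 8.0)
        counts = prof.raw_counts["gas"] * prof.n_frames
        tol = 3.0 / np.sqrt(np.maximum(counts[sel], 1))
        assert (np.abs(prof.g["gas"][sel] - 1.0) < tol).all()

    def test_delta_shell(self):
        """6 contributors at exactly 2.4 Å occupy a single shell."""
        box = 30.0
        center = np.full(3, box / 2)
        dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                         [0, 0, 1], [0, 0, -1]], float)
        pos = np.vstack([center, center + 2.4 * dirs])[None]
        traj = Trajectory(pos, [0.0], [[box] * 3],
                          groups={"center": [0], "shell": 1 + np.arange(6)})
        res = ResidencyMatrix(np.array([0]), np.ones((1, 1), bool), [0.0])
        prof = rdf_decomposed(traj, res, "center", ["shell"], r_max=5.0,
                              dr=0.25)
        occupied = np.nonzero(prof.g["shell"])[0]
        assert occupied.size == 1
        assert abs(prof.r[occupied[0]] - 2.4) <= 0.125

    def test_matches_brute_force_pair_histogram(self):
        """Profile equals a brute-force per-frame minimum-image pair
        histogram with identical normalization on a 20-particle fixture."""
        rng = np.random.default_rng(149)
        box = 20.0
        n_frames, n_c, n_g = 4, 3, 17
        pos = rng.uniform(0, box, (n_frames, n_c + n_g, 3))
        traj = Trajectory(pos, np.arange(float(n_frames)),
                          np.tile([box] * 3, (n_frames, 1)),
                          groups={"centers": np.arange(n_c),
                                  "gas": n_c + np.arange(n_g)})
        res = ResidencyMatrix(np.arange(n_c), np.ones((n_c, n_frames), bool),
                              traj.times)
        dr, r_max = 0.5, 8.0
        prof = rdf_decomposed(traj, res, "centers", ["gas"], r_max, dr)

        edges = dr * np.arange(int(r_max / dr) + 1)
        counts = np.zeros(edges.size - 1)
        for f in range(n_frames):
            for i in range(n_c):
                for j in range(n_c, n_c + n_g):
                    d = pos[f, j] - pos[f, i]
                    d -= box * np.round(d / box)
                    r = np.linalg.norm(d)
                    if r < r_max:
                        counts[int(r // dr)] += 1
        shell_vol = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        expected = counts / n_frames / (n_c * n_g * shell_vol / box ** 3)
        np.testing.assert_allclose(prof.g["gas"], expected, atol=1e-10)

    def test_no_inside_centers_is_error(self):
        traj, res = ideal_gas_fixture(n_contrib=10, n_frames=2)
        res.inside[:] = False
        with pytest.raises(ValueError, match="inside"):
            rdf_decomposed(traj, res, "center", ["gas"], 5.0, 0.5)


class TestFirstShellRadius:
    @staticmethod
    def profile_from_curve(r, g):
        return RDFProfile(r=r, g={"w": g}, dr=float(r[1] - r[0]),
                          n_centers=1.0, n_contributors={"w": 100},
                          n_frames=1, box_volume=1000.0)

    def test_constructed_peak_and_dip(self):
        r = np.arange(0.5, 6.0, 0.1)
        g = 1.0 + 3.0 * np.exp(-((r - 2.4) / 0.3) ** 2) \
            - 0.8 * np.exp(-((r - 3.0) / 0.2) ** 2)
        prof = self.profile_from_curve(r, g)
        assert first_shell_radius(prof, "w") == pytest.approx(3.0, abs=0.15)

    def test_flat_profile_is_error(self):
        prof = self.profile_from_curve(np.arange(0.5, 6.0, 0.1),
                                       np.ones(55))
        with pytest.raises(ValueError, match="no first shell"):
            first_shell_radius(prof, "w")

    def test_two_peak_analytic_minimum(self):
        """Two-peak synthetic g(r): detected minimum within one dr of the
        analytic minimum of the generating function."""
        r = np.arange(1.0, 8.0, 0.05)
        g = (2.5 * np.exp(-((r - 2.5) / 0.35) ** 2)
             + 1.2 * np.exp(-((r - 4.5) / 0.5) ** 2) + 0.2)
        rf = np.arange(2.5, 4.5, 1e-4)
        gf = (2.5 * np.exp(-((rf - 2.5) / 0.35) ** 2)
              + 1.2 * np.exp(-((rf - 4.5) / 0.5) ** 2) + 0.2)
        analytic = rf[np.argmin(gf)]
        prof = self.profile_from_curve(r, g)
        assert abs(first_shell_radius(prof, "w") - analytic) <= 2 * 0.05


class TestCoordinationNumbers:
    def test_fixed_shell(self):
        box = 30.0
        center = np.full(3, box / 2)
        dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                         [0, 0, 1], [0, 0, -1]], float)
        pos = np.vstack([center, center + 2.0 * dirs])[None]
        traj = Trajectory(pos, [0.0], [[box] * 3],
                          groups={"cation": [0], "water": 1 + np.arange(6)})
        res = ResidencyMatrix(np.array([0]), np.ones((1, 1), bool), [0.0])
        table = coordination_numbers(traj, res, "cation", ["water"],
                                     {"water": 3.2})
        assert table.mean["water"] == 6.0
        assert table.sd["water"] == 0.0

    def test_all_beyond_radius(self):
        box = 30.0
        pos = np.array([[[15.0, 15, 15], [25.0, 15, 15]]])
        traj = Trajectory(pos, [0.0], [[box] * 3],
                          groups={"cation": [0], "water": [1]})
        res = ResidencyMatrix(np.array([0]), np.ones((1, 1), bool), [0.0])
        table = coordination_numbers(traj, res, "cation", ["water"],
                                     {"water": 3.0})
        assert table.mean["water"] == 0.0

    def test_direct_equals_brute_force_and_rdf_integration(self):
        """Random fixture: direct neighbor counting equals brute force, and
        equals 4πρ∫g(r)r²dr within 2% on the matched RDF."""
        rng = np.random.default_rng(151)
        box = 25.0
        n_frames, n_g = 30, 800
        pos = np.empty((n_frames, n_g + 1, 3))
        pos[:, 0, :] = box / 2
        pos[:, 1:, :] = rng.uniform(0, box, (n_frames, n_g, 3))
        traj = Trajectory(pos, np.arange(float(n_frames)),
                          np.tile([box] * 3, (n_frames, 1)),
                          groups={"cation": [0], "gas": 1 + np.arange(n_g)})
        res = ResidencyMatrix(np.array([0]), np.ones((1, n_frames), bool),
                              traj.times)
        dr = 0.25
        rc = 4.0  # on a bin edge
        table = coordination_numbers(traj, res, "cation", ["gas"],
                                     {"gas": rc})
        # brute force
        total = 0
        for f in range(n_frames):
            d = pos[f, 1:] - pos[f, 0]
            d -= box * np.round(d / box)
            total += (np.linalg.norm(d, axis=1) <= rc).sum()
        assert table.mean["gas"] == pytest.approx(total / n_frames)
        # RDF integration route
        prof = rdf_decomposed(traj, res, "cation", ["gas"], r_max=8.0, dr=dr)
        integ = coordination_from_rdf(prof, "gas", rc)
        assert integ == pytest.approx(table.mean["gas"], rel=0.02)


class TestHBonds:
    def test_linear_bond_counted(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]])
        n, bonds = count_hbonds(pos, donors=[(0, 1)], acceptors=[2],
                                criteria=HBondCriteria(3.5, 150.0))
        assert n == 1
        assert bonds == [(0, 1, 2)]

    def test_bent_geometry_rejected(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 2.9, 0]])
        n, _ = count_hbonds(pos, donors=[(0, 1)], acceptors=[2],
                            criteria=HBondCriteria(3.5, 150.0))
        assert n == 0

    def test_matches_exhaustive_geometric_check(self):
        """30 random donor/acceptor triplets vs a direct geometric check."""
        rng = np.random.default_rng(157)
        pos = rng.uniform(0, 8, (90, 3))
        donors = [(3 * i, 3 * i + 1) for i in range(30)]
        acceptors = [3 * i + 2 for i in range(30)]
        crit = HBondCriteria(3.5, 140.0)
        n, bonds = count_hbonds(pos, donors, acceptors, crit)
        expected = set()
        for d, h in donors:
            for a in acceptors:
                if a in (d, h):
                    continue
                if np.linalg.norm(pos[a] - pos[d]) > crit.distance_cutoff:
                    continue
                v1 = pos[d] - pos[h]
                v2 = pos[a] - pos[h]
                ang = np.degrees(np.arccos(np.clip(
                    v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2),
                    -1, 1)))
                if ang >= crit.angle_cutoff:
                    expected.add((d, h, a))
        assert set(bonds) == expected
        assert n == len(expected)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(163)
        pos = rng.uniform(0, 6, (30, 3))
        donors = [(0, 1), (5, 6), (10, 11)]
        acceptors = [2, 7, 12, 20]
        n1, _ = count_hbonds(pos, donors, acceptors)
        rot = Rotation.random(random_state=1).as_matrix()
        n2, _ = count_hbonds(pos @ rot.T + np.array([3.0, -2.0, 7.0]),
                             donors, acceptors)
        assert n1 == n2

    def test_malformed_donor(self):
        with pytest.raises(ValueError, match="donor"):
            count_hbonds(np.zeros((3, 3)), donors=[(0, 99)], acceptors=[2])


class TestTheoreticalMaxHBonds:
    def test_eight_ring_tube(self):
        # eight stacked rings, 12 bonds per interface
        assert theoretical_max_hbonds(8, 12) == 84

    def test_single_ring_no_interface(self):
        assert theoretical_max_hbonds(1, 12) == 0

    def test_three_rings(self):
        assert theoretical_max_hbonds(3, 12) == 24

    def test_linear_in_both_arguments(self):
        rng = np.random.default_rng(167)
        for _ in range(20):
            n = int(rng.integers(1, 30))
            b = int(rng.integers(0, 30))
            assert theoretical_max_hbonds(n + 1, b) \
                - theoretical_max_hbonds(n, b) == b
            assert theoretical_max_hbonds(n, 2 * b) \
                == 2 * theoretical_max_hbonds(n, b)
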