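"""Geometry operations: axes, angles, RMSD, distances, sites, R_g, SASA."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from cadmech.geometry import (
    DegenerateAxisError,
    bend_angle,
    buried_surface,
    distance_series,
    kabsch_rmsd,
    locate_ca_sites,
    orientation_map,
    principal_axis,
    radius_of_gyration,
    running_average,
    shrake_rupley_sasa,
)
from cadmech.io_formats import Atom, DomainDefinition, Structure, Trajectory

from conftest import make_rod


def _atom(i, pos, element="C", name="CA", resname="GLY", hetero=False, chain="A", mass=12.011):
    return Atom(i, name, element, resname, i, chain, "", 1.0,
                tuple(float(c) for c in pos), mass, hetero)


def _point_structure(points, **kw):
    return Structure([_atom(i + 1, p, **kw) for i, p in enumerate(points)])


class TestPrincipalAxis:
    def test_rod_along_z_gives_unit_z(self, rod_structure):
        s, dom = rod_structure
        axis = principal_axis(s, dom)
        assert np.allclose(axis, [0, 0, 1], atol=0.02)

    @pytest.mark.parametrize("seed", range(5))
    def test_rotated_rod_gives_rotated_axis(self, seed):
        R = Rotation.random(random_state=seed)
        atoms = make_rod(n=12)
        s = Structure(atoms)
        dom = DomainDefinition("rod", "A", 1, 12)
        a0 = principal_axis(s, dom)
        a1 = principal_axis(s.transformed(R.as_matrix(), [1.0, -2.0, 3.0]), dom)
        assert np.allclose(a1, R.as_matrix() @ a0, atol=1e-6)

    def test_spherical_cloud_raises_degeneracy(self):
        rng = np.random.default_rng(0)
        s = _point_structure(rng.normal(size=(500, 3)))
        with pytest.raises(DegenerateAxisError):
            principal_axis(s, DomainDefinition("blob", "A", 1, 500))


class TestBendAngle:
    def test_collinear_duplicate_is_zero(self):
        atoms = make_rod(n=12) + make_rod(n=12, origin=(0, 0, 60), start_res=13)
        s = Structure(atoms)
        a = DomainDefinition("A1", "A", 1, 12)
        b = DomainDefinition("A2", "A", 13, 24)
        assert bend_angle(s, a, b) == pytest.approx(0.0, abs=2.0)

    @pytest.mark.parametrize("angle", [30.0, 90.0, 150.0])
    def test_constructed_angle_recovered(self, angle):
        rad = np.radians(angle)
        atoms = make_rod(n=12) + make_rod(
            n=12, axis=(np.sin(rad), 0, np.cos(rad)), origin=(0, 0, 50), start_res=13
        )
        s = Structure(atoms)
        got = bend_angle(s, DomainDefinition("A1", "A", 1, 12), DomainDefinition("A2", "A", 13, 24))
        assert got == pytest.approx(angle, abs=2.0)

    def test_invariant_under_rigid_motion(self):
        atoms = make_rod(n=12) + make_rod(n=12, axis=(1, 0, 0), origin=(0, 0, 50), start_res=13)
        s = Structure(atoms)
        a = DomainDefinition("A1", "A", 1, 12)
        b = DomainDefinition("A2", "A", 13, 24)
        R = Rotation.random(random_state=3).as_matrix()
        moved = s.transformed(R, [-7.0, 11.0, 2.0])
        assert bend_angle(moved, a, b) == pytest.approx(bend_angle(s, a, b), abs=1e-6)


class TestOrientationMap:
    def _traj(self, probe_axis, n_frames=5):
        frames = []
        for i in range(n_frames):
            atoms = make_rod(n=12) + make_rod(
                n=12, axis=probe_axis, origin=(60, 0, 0), start_res=13
            )
            frames.append(Structure(atoms, model_id=i + 1))
        return Trajectory(frames=frames, times=np.arange(n_frames, dtype=float))

    def test_parallel_probe_concentrates_at_origin(self):
        traj = self._traj((0, 0, 1))
        omap = orientation_map(
            traj, DomainDefinition("ref", "A", 1, 12), DomainDefinition("probe", "A", 13, 24)
        )
        assert omap.probabilities.sum() == pytest.approx(1.0)
        hot = np.unravel_index(np.argmax(omap.probabilities), omap.probabilities.shape)
        centers = (omap.edges[:-1] + omap.edges[1:]) / 2
        assert omap.probabilities[hot] == 1.0
        assert abs(centers[hot[0]]) <= 2.0 / 50 and abs(centers[hot[1]]) <= 2.0 / 50

    def test_perpendicular_probe_sits_on_unit_circle(self):
        traj = self._traj((1, 0, 0))
        omap = orientation_map(
            traj, DomainDefinition("ref", "A", 1, 12), DomainDefinition("probe", "A", 13, 24)
        )
        radii = np.hypot(omap.points[:, 0], omap.points[:, 1])
        assert np.all(np.abs(radii - 1.0) < 2.0 / 50)
        assert radii.max() <= 1.0 + 1e-9
        azimuth = np.arctan2(omap.points[:, 1], omap.points[:, 0])
        assert np.ptp(azimuth) < 1e-9

    def test_invalid_stride_is_error(self):
        traj = self._traj((0, 0, 1), n_frames=2)
        with pytest.raises(ValueError, match="stride"):
            orientation_map(
                traj,
                DomainDefinition("ref", "A", 1, 12),
                DomainDefinition("probe", "A", 13, 24),
                stride_ps=-5.0,
            )


def _brute_force_rmsd(A, B):
    """Independent numerical optimum: coarse random-rotation search refined
    by Nelder-Mead on the rotation vector."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = A - B @ R.T
        return np.sqrt((d ** 2).sum() / len(A))

    grid = Rotation.random(4000, random_state=0)
    vals = [rmsd_of(r.as_rotvec()) for r in grid]
    best = grid[int(np.argmin(vals))].as_rotvec()
    res = minimize(rmsd_of, best, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
    return float(res.fun)


class TestKabschRmsd:
    def test_identical_coordinates_give_zero(self, rod_structure):
        s, _ = rod_structure
        assert kabsch_rmsd(s, s) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_gives_zero(self, rod_structure):
        s, _ = rod_structure
        R = Rotation.random(random_state=1).as_matrix()
        assert kabsch_rmsd(s, s.transformed(R, [5.0, -3.0, 8.0])) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(scale=5.0, size=(10, 3))
        B = A + rng.normal(scale=1.0, size=(10, 3))
        sa = _point_structure(A)
        sb = _point_structure(B)
        assert kabsch_rmsd(sa, sb) == pytest.approx(_brute_force_rmsd(A, B), abs=1e-3)

    def test_superposed_never_exceeds_unsuperposed(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            A = rng.normal(scale=4.0, size=(8, 3))
            B = rng.normal(scale=4.0, size=(8, 3))
            raw = float(np.sqrt(((A - B) ** 2).sum() / len(A)))
            assert kabsch_rmsd(_point_structure(A), _point_structure(B)) <= raw + 1e-9

    def test_mismatched_selections_error(self, rod_structure):
        s, _ = rod_structure
        other = Structure(make_rod(n=10))
        with pytest.raises(ValueError, match="one-to-one"):
            kabsch_rmsd(s, other)


class TestDistanceSeries:
    @staticmethod
    def _static_traj(points_a, points_b, n=6):
        frames = []
        for i in range(n):
            frames.append(Structure([
                _atom(1, points_a), _atom(2, points_b),
            ], model_id=i + 1))
        return Trajectory(frames=frames, times=np.arange(n, dtype=float))

    def test_static_pair_gives_constant_distance(self):
        traj = self._static_traj((0, 0, 0), (0, 3, 4))
        ds = distance_series(traj, ("A", 1, "CA"), ("A", 2, "CA"))
        np.testing.assert_allclose(ds.values, 5.0)

    def test_running_average_of_ramp_is_ramp_away_from_edges(self):
        ramp = np.arange(50, dtype=float)
        sm = running_average(ramp, 7)
        np.testing.assert_allclose(sm[3:-3], ramp[3:-3], atol=1e-12)

    def test_unresolvable_selector_names_frame(self):
        traj = self._static_traj((0, 0, 0), (1, 0, 0))
        with pytest.raises(ValueError, match="frame 0"):
            distance_series(traj, ("A", 1, "CA"), ("B", 9, "XX"))


class TestCaSites:
    def test_structure_without_calcium_gives_empty_set(self, rod_structure):
        s, _ = rod_structure
        sites = locate_ca_sites(s, (5, 8))
        assert sites.n_sites == 0 and sites.d23 is None

    def test_sites_labeled_along_first_repeat_axis(self, bent_synthetic):
        s, truth, d = bent_synthetic
        linker = (d["linker"].first_residue, d["linker"].last_residue)
        sites = locate_ca_sites(s, linker)
        # site 1 nearest the first repeat's base (most negative z here)
        z = [p[2] for p in sites.positions]
        assert z == sorted(z)

    def test_d23_invariant_under_rigid_motion(self, bent_synthetic):
        s, truth, d = bent_synthetic
        linker = (d["linker"].first_residue, d["linker"].last_residue)
        R = Rotation.random(random_state=5).as_matrix()
        moved = s.transformed(R, [3.0, 3.0, -9.0])
        assert locate_ca_sites(moved, linker).d23 == pytest.approx(
            locate_ca_sites(s, linker).d23, abs=1e-6
        )


class TestRadiusOfGyration:
    def test_two_equal_masses_two_angstrom_apart(self):
        s = _point_structure([(0, 0, 0), (2, 0, 0)])
        assert radius_of_gyration(s) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_sphere_matches_closed_form(self):
        rng = np.random.default_rng(4)
        R = 20.0
        pts = rng.normal(size=(4000, 3))
        pts = pts / np.linalg.norm(pts, axis=1)[:, None] * (R * rng.uniform(0, 1, 4000) ** (1 / 3))[:, None]
        s = _point_structure(pts)
        assert radius_of_gyration(s) == pytest.approx(np.sqrt(3 / 5) * R, rel=0.02)

    def test_empty_structure_is_error(self):
        with pytest.raises(ValueError):
            radius_of_gyration(Structure(atoms=[]))

    def test_invariant_under_rigid_motion(self, bent_synthetic):
        s, _, _ = bent_synthetic
        R = Rotation.random(random_state=9).as_matrix()
        moved = s.transformed(R, [100.0, -50.0, 1.0])
        assert radius_of_gyration(moved) == pytest.approx(radius_of_gyration(s), abs=1e-6)


class TestSurfaceArea:
    def test_isolated_atom_matches_closed_form(self):
        # Bondi radius of carbon is 1.70 Å; probe 1.4 Å
        s = _point_structure([(0.0, 0.0, 0.0)])
        expected = 4 * np.pi * (1.70 + 1.4) ** 2
        assert shrake_rupley_sasa(s)[0] == pytest.approx(expected, rel=0.02)

    def test_distant_domains_bury_nothing(self):
        atoms = make_rod(n=6) + make_rod(n=6, origin=(100, 100, 0), start_res=7)
        s = Structure(atoms)
        out = buried_surface(s, DomainDefinition("a", "A", 1, 6), DomainDefinition("b", "A", 7, 12))
        assert out["bsa"] == pytest.approx(0.0, abs=1e-6)
        assert out["interface_residues"] == []

    def test_bsa_symmetric_and_nonnegative(self, bent_synthetic):
        s, _, d = bent_synthetic
        ab = buried_surface(s, d["domain1"], d["domain2"])
        ba = buried_surface(s, d["domain2"], d["domain1"])
        assert ab["bsa"] == pytest.approx(ba["bsa"], abs=1e-6)
        assert ab["bsa"] >= 0.0

    def test_halving_convention(self, bent_synthetic):
        s, _, d = bent_synthetic
        half = buried_surface(s, d["domain1"], d["domain2"], halve=True)["bsa"]
        full = buried_surface(s, d["domain1"], d["domain2"], halve=False)["bsa"]
        assert full == pytest.approx(2 * half, rel=1e-9)

    def test_bsa_stable_under_rigid_motion(self, bent_synthetic):
        # Shrake-Rupley point grids are fixed in the lab frame, so rotation
        # invariance holds only to the discretization error (~1%)
        s, _, d = bent_synthetic
        R = Rotation.random(random_state=2).as_matrix()
        moved = s.transformed(R, [0.0, 0.0, 0.0])
        a = buried_surface(s, d["domain1"], d["domain2"])["bsa"]
        b = buried_surface(moved, d["domain1"], d["domain2"])["bsa"]
        assert b == pytest.approx(a, rel=0.05, abs=2.0)
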