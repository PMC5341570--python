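"""Trajectory geometry metrics: superposition, RMSD, Rg, RMSF, contacts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import point_topology, point_trajectory
from rindyn.errors import AnalysisError, SuperpositionError
from rindyn.metrics import (
    com_distance,
    compare_profiles,
    contact_count,
    dihedral_series,
    hydration_count,
    kabsch_superpose,
    radius_of_gyration,
    rmsd_series,
    rmsf,
)
from rindyn.structure import Atom, Residue, Topology, Trajectory


class TestKabsch:
    def test_identity_for_identical_coordinates(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((10, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-8)

    def test_recovers_exact_rigid_rotation(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((8, 3))
        r_applied = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        mobile = pts @ r_applied.T
        sup = kabsch_superpose(pts, mobile)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.rotation @ r_applied, np.eye(3), atol=1e-8)

    def test_proper_rotation_always(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.standard_normal((6, 3))
            b = rng.standard_normal((6, 3))
            sup = kabsch_superpose(a, b)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_optimality_against_random_rotation_sampling(self):
        # brute-force oracle: no random rotation beats the Kabsch optimum
        rng = np.random.default_rng(3)
        rot_mats = Rotation.random(1000, rng=rng).as_matrix()
        for _ in range(50):
            ref = rng.standard_normal((10, 3))
            mob = rng.standard_normal((10, 3))
            best = kabsch_superpose(ref, mob).rmsd
            ref_c = ref - ref.mean(axis=0)
            mob_c = mob - mob.mean(axis=0)
            rotated = np.einsum("rij,nj->rni", rot_mats, mob_c)
            sampled = np.sqrt(np.mean(np.sum(
                (rotated - ref_c[None]) ** 2, axis=2), axis=1))
            assert best <= sampled.min() + 1e-12

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(SuperpositionError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(SuperpositionError):
            kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_copies_of_reference_are_zero(self):
        rng = np.random.default_rng(4)
        ref = rng.standard_normal((6, 3))
        traj = point_trajectory(np.repeat(ref[None], 5, axis=0))
        values = rmsd_series(traj, ref, np.arange(6)).values
        assert np.allclose(values, 0.0, atol=1e-10)

    def test_rigidly_rotated_copies_are_zero(self):
        rng = np.random.default_rng(5)
        ref = rng.standard_normal((6, 3))
        frames = np.array([ref @ Rotation.from_euler("xyz", a).as_matrix().T + 0.3
                           for a in rng.uniform(-2, 2, (5, 3))])
        traj = point_trajectory(frames)
        assert np.allclose(rmsd_series(traj, ref, np.arange(6)).values, 0.0,
                           atol=1e-9)

    def test_single_displaced_atom_closed_form(self):
        # moving one atom by d changes RMSD to d/sqrt(n) only in the
        # unfitted frame; verify against the explicit post-fit optimum
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                        [1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]])
        moved = ref.copy()
        d = 0.05
        moved[0, 0] -= d
        traj = point_trajectory(moved[None])
        got = rmsd_series(traj, ref, np.arange(8)).values[0]
        assert got <= d / np.sqrt(8) + 1e-12  # fitting can only reduce it
        assert got == pytest.approx(kabsch_superpose(ref, moved).rmsd, abs=1e-12)


class TestRadiusOfGyration:
    def test_unit_cube_closed_form(self):
        pts = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                       dtype=float)
        traj = point_trajectory(pts)
        rg = radius_of_gyration(traj, np.arange(8), mass_weighted=False).values[0]
        assert rg == pytest.approx(np.sqrt(3) / 2, abs=1e-12)

    def test_single_atom_zero(self):
        traj = point_trajectory(np.array([[1.0, 2.0, 3.0]]))
        assert radius_of_gyration(traj, np.array([0])).values[0] == 0.0

    def test_mass_weighting_matches_direct_summation(self):
        atoms = [Atom("N", "N", 0), Atom("C1", "C", 1), Atom("O", "O", 2)]
        residues = [Residue("LIG", i + 1, "A", [i]) for i in range(3)]
        top = Topology(atoms, residues)
        xyz = np.array([[0.0, 0, 0], [0.5, 0, 0], [0, 0.8, 0]])
        traj = Trajectory(xyz[None], [0.0], top)
        m = top.masses
        com = (m[:, None] * xyz).sum(axis=0) / m.sum()
        expected = np.sqrt((m * ((xyz - com) ** 2).sum(axis=1)).sum() / m.sum())
        got = radius_of_gyration(traj, np.arange(3), mass_weighted=True).values[0]
        assert got == pytest.approx(expected, abs=1e-12)
        unweighted = radius_of_gyration(traj, np.arange(3),
                                        mass_weighted=False).values[0]
        assert got != pytest.approx(unweighted, abs=1e-6)

    def test_invariance_and_scaling(self):
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((7, 3))
        rot = Rotation.from_euler("xyz", [0.3, 1.1, -0.4]).as_matrix()
        rg0 = radius_of_gyration(point_trajectory(pts), np.arange(7)).values[0]
        rg1 = radius_of_gyration(point_trajectory(pts @ rot.T + 5.0),
                                 np.arange(7)).values[0]
        rg2 = radius_of_gyration(point_trajectory(pts * 3.0), np.arange(7)).values[0]
        assert rg1 == pytest.approx(rg0, abs=1e-10)
        assert rg2 == pytest.approx(3.0 * rg0, abs=1e-10)


class TestRmsf:
    def test_static_trajectory_zero(self):
        pts = np.random.default_rng(7).standard_normal((5, 3))
        traj = point_trajectory(np.repeat(pts[None], 4, axis=0))
        assert np.allclose(rmsf(traj, np.arange(5)), 0.0, atol=1e-12)

    def test_single_oscillating_atom_closed_form(self):
        base = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                         [1, 1, 1], [2, 1, 0]])
        d = 0.02
        up, down = base.copy(), base.copy()
        up[5, 0] += d
        down[5, 0] -= d
        traj = point_trajectory(np.stack([up, down]))
        # fit on the static atoms so no global motion is removed from atom 5
        values = rmsf(traj, np.arange(6), fit_selection=np.arange(5))
        assert values[5] == pytest.approx(d, rel=1e-6)
        assert np.allclose(values[:5], 0.0, atol=1e-9)

    def test_global_rotation_removed(self):
        rng = np.random.default_rng(8)
        pts = rng.standard_normal((6, 3))
        frames = np.array([pts @ Rotation.from_euler("z", a).as_matrix().T
                           for a in np.linspace(0, 1.0, 5)])
        traj = point_trajectory(frames)
        assert np.abs(rmsf(traj, np.arange(6))).max() < 1e-6


class TestCompareProfiles:
    def test_identical_profiles(self):
        a = np.array([1.0, 2.0, 4.0, 8.0])
        res = compare_profiles(a, a)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.residual_variance_s2 == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated(self):
        a = np.array([1.0, 2.0, 3.0])
        assert compare_profiles(a, -a).pearson_r == pytest.approx(-1.0)

    def test_hand_least_squares(self):
        # pairs (1,2),(2,3),(3,5): slope 1.5, intercept 1/3, r ~ 0.9820
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 3.0, 5.0])
        res = compare_profiles(a, b)
        assert res.slope == pytest.approx(1.5)
        assert res.intercept == pytest.approx(1.0 / 3.0)
        assert res.pearson_r == pytest.approx(0.9820, abs=5e-4)
        resid = b - (1.5 * a + 1.0 / 3.0)
        assert res.residual_variance_s2 == pytest.approx((resid ** 2).sum() / 1)

    def test_affine_invariance_of_r(self):
        a = np.array([0.5, 1.0, 2.5, 3.0, 4.5])
        for c, k in ((2.0, 1.0), (-0.5, 3.0)):
            assert abs(compare_profiles(a, a * c + k).pearson_r) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(AnalysisError):
            compare_profiles(np.ones(5), np.arange(5.0))


class TestDistancesContacts:
    def test_com_distance_trivial_and_weighted(self):
        atoms = [Atom("C1", "C", 0), Atom("O1", "O", 1), Atom("C2", "C", 2)]
        residues = [Residue("LIG", i + 1, "A", [i]) for i in range(3)]
        top = Topology(atoms, residues)
        xyz = np.array([[0.0, 0, 0], [1.0, 0, 0], [4.0, 0, 0]])
        traj = Trajectory(xyz[None], [0.0], top)
        assert com_distance(traj, [0], [0]).values[0] == 0.0
        assert com_distance(traj, [0], [2]).values[0] == pytest.approx(4.0)
        m = top.masses
        com_ab = (m[0] * xyz[0] + m[1] * xyz[1]) / (m[0] + m[1])
        expected = np.linalg.norm(com_ab - xyz[2])
        assert com_distance(traj, [0, 1], [2]).values[0] == pytest.approx(expected)

    def test_contact_count_enumerations(self):
        xyz = np.array([[0.0, 0, 0], [0.5, 0, 0], [1.0, 0, 0]])
        traj = point_trajectory(xyz)
        sel = np.arange(3)
        assert contact_count(traj, sel, sel, 0.6).values[0] == 2
        assert contact_count(traj, sel, sel, 0.4).values[0] == 0

    def test_contact_count_against_bruteforce(self):
        rng = np.random.default_rng(9)
        xyz = rng.uniform(0, 1.5, (50, 3))
        traj = point_trajectory(xyz)
        cutoff = 0.4
        brute = sum(1 for i in range(50) for j in range(i + 1, 50)
                    if np.linalg.norm(xyz[i] - xyz[j]) < cutoff)
        got = contact_count(traj, np.arange(50), np.arange(50), cutoff).values[0]
        assert got == brute


class TestDihedrals:
    def test_planar_cis_and_trans(self):
        cis = np.array([[0.0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]])
        trans = np.array([[0.0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]])
        assert dihedral_series(point_trajectory(cis), np.arange(4)).values[0] \
            == pytest.approx(0.0, abs=1e-9)
        assert abs(dihedral_series(point_trajectory(trans), np.arange(4)).values[0]) \
            == pytest.approx(180.0, abs=1e-9)

    def test_colinear_triple_rejected(self):
        bad = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]])
        with pytest.raises(AnalysisError):
            dihedral_series(point_trajectory(bad), np.arange(4))


class TestHydration:
    def _system(self, water_positions):
        atoms = [Atom("C1", "C", 0)]
        residues = [Residue("LIG", 1, "A", [0])]
        coords = [[0.0, 0.0, 0.0]]
        for w, pos in enumerate(water_positions):
            ridx = len(residues)
            residues.append(Residue("HOH", 100 + w, "W", [len(atoms)],
                                    is_water=True, is_hetero=True))
            atoms.append(Atom("OW", "O", ridx))
            coords.append(pos)
        top = Topology(atoms, residues)
        return Trajectory(np.asarray(coords, float)[None], [0.0], top)

    def test_no_waters(self):
        traj = self._system([])
        assert hydration_count(traj, np.array([0])).values[0] == 0

    def test_shell_boundary(self):
        traj = self._system([[0.3, 0, 0], [0.5, 0, 0]])
        assert hydration_count(traj, np.array([0]), cutoff=0.4).values[0] == 1

    def test_against_bruteforce(self):
        rng = np.random.default_rng(10)
        waters = rng.uniform(-1, 1, (100, 3))
        traj = self._system(waters)
        brute = sum(1 for w in waters if np.linalg.norm(w) < 0.4)
        assert hydration_count(traj, np.array([0]), cutoff=0.4).values[0] == brute
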