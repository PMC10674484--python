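"""Shape descriptors: Rg, Kirkwood Rh, volumes, RMSF, PDB round trips."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lipoagg import (
    Trajectory,
    build_helix,
    gyration_volume,
    kirkwood_rh,
    radius_of_gyration,
    read_structure,
    rmsf,
    sample_uniform_ball,
    trajectory_summary,
    volume_from_radius,
    write_geometry_pdb,
    write_pdb,
)


def brute_force_rg(xyz, masses):
    com = (xyz * masses[:, None]).sum(axis=0) / masses.sum()
    acc = 0.0
    for r, m in zip(xyz, masses):
        acc += m * np.dot(r - com, r - com)
    return np.sqrt(acc / masses.sum())


def brute_force_kirkwood(xyz):
    inv, n = 0.0, len(xyz)
    for i in range(n):
        for j in range(i + 1, n):
            inv += 1.0 / np.linalg.norm(xyz[i] - xyz[j])
    return 1.0 / (inv / (n * (n - 1) / 2))


def kabsch(mobile, ref):
    """Independent SVD-based rigid superposition."""
    mc, rc = mobile.mean(axis=0), ref.mean(axis=0)
    h = (mobile - mc).T @ (ref - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (mobile - mc) @ rot.T + rc


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_symmetric_dumbbell(self):
        xyz = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        assert radius_of_gyration(xyz) == pytest.approx(5.0)

    def test_matches_direct_sum(self):
        helix = build_helix(32)
        rng = np.random.default_rng(0)
        masses = rng.uniform(1.0, 16.0, size=32)
        assert radius_of_gyration(helix.coordinates, masses) == pytest.approx(
            brute_force_rg(helix.coordinates, masses), rel=1e-10)

    def test_unweighted_mode_ignores_masses(self):
        helix = build_helix(16)
        heavy = np.linspace(1, 100, 16)
        assert radius_of_gyration(helix.coordinates, heavy, mass_weighted=False) == \
            pytest.approx(radius_of_gyration(helix.coordinates), rel=1e-12)


class TestKirkwoodRh:
    def test_single_pair_identity(self):
        xyz = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        assert kirkwood_rh(xyz) == pytest.approx(10.0)

    def test_square_of_side_ten(self):
        xyz = np.array([[0.0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]])
        expected = 1.0 / ((4 / 10 + 2 / (10 * np.sqrt(2))) / 6)
        assert expected == pytest.approx(11.08, abs=0.005)
        assert kirkwood_rh(xyz) == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(42)
        xyz = rng.normal(scale=8.0, size=(200, 3))
        assert kirkwood_rh(xyz) == pytest.approx(brute_force_kirkwood(xyz), rel=1e-10)

    def test_element_selection(self):
        xyz = np.array([[0.0, 0, 0], [10, 0, 0], [500.0, 0, 0]])
        elements = ("C", "C", "N")
        assert kirkwood_rh(xyz, elements, selection="C") == pytest.approx(10.0)

    def test_coincident_atoms_rejected(self):
        xyz = np.array([[0.0, 0, 0], [0.0, 0, 0], [10, 0, 0]])
        with pytest.raises(ValueError, match="coincident.*0 and 1"):
            kirkwood_rh(xyz)


class TestRigidMotionAndScaling:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        xyz = rng.normal(scale=5.0, size=(60, 3))
        rot = Rotation.random(rng=rng)
        moved = rot.apply(xyz) + rng.uniform(-50, 50, size=3)
        assert radius_of_gyration(moved) == pytest.approx(
            radius_of_gyration(xyz), rel=1e-9)
        assert kirkwood_rh(moved) == pytest.approx(kirkwood_rh(xyz), rel=1e-9)

    def test_homogeneity_degree_one(self):
        xyz = build_helix(24).coordinates
        assert radius_of_gyration(3.0 * xyz) == pytest.approx(
            3.0 * radius_of_gyration(xyz), rel=1e-12)
        assert kirkwood_rh(3.0 * xyz) == pytest.approx(
            3.0 * kirkwood_rh(xyz), rel=1e-12)


@pytest.fixture(scope="module")
def ball():
    return sample_uniform_ball(20_000, 10.0, seed=123)


class TestUniformBallClosedForms:
    def test_rg_approaches_sqrt_three_fifths_radius(self, ball):
        assert radius_of_gyration(ball.coordinates) == pytest.approx(
            ball.reference_values["Rg_A"], rel=0.01)

    def test_kirkwood_approaches_five_sixths_radius(self, ball):
        assert kirkwood_rh(ball.coordinates) == pytest.approx(
            ball.reference_values["Rh_A"], rel=0.02)


class TestGyrationVolume:
    @pytest.mark.parametrize("rg, vol", [(13.9, 11.3), (45.2, 386.8), (10.0, 4.18879)])
    def test_sphere_volumes(self, rg, vol):
        assert gyration_volume(rg) == pytest.approx(vol, abs=0.1)


class TestRmsf:
    @staticmethod
    def make_traj(frames, names=None):
        n = frames.shape[1]
        return Trajectory(
            frames=frames,
            elements=tuple(["C"] * n),
            masses=np.ones(n),
            atom_names=tuple(names or ["CA"] * n),
            residue_ids=np.arange(1, n + 1),
        )

    def test_identical_frames_give_zero(self):
        base = build_helix(12).coordinates
        traj = self.make_traj(np.stack([base] * 5))
        assert np.max(rmsf(traj)) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotations_removed_by_superposition(self):
        base = build_helix(15).coordinates
        rng = np.random.default_rng(7)
        frames = np.stack([
            Rotation.random(rng=rng).apply(base) + rng.uniform(-20, 20, 3)
            for _ in range(8)
        ])
        traj = self.make_traj(frames)
        fluct = rmsf(traj, superpose=True)
        # cross-check the package alignment against an independent Kabsch
        aligned = np.stack([kabsch(f, frames.mean(axis=0)) for f in frames])
        assert np.max(np.std(aligned, axis=0)) < 1e-6
        assert np.max(fluct) < 1e-6

    def test_isotropic_jitter_converges_to_sd_times_sqrt3(self):
        base = build_helix(6).coordinates
        sd = 0.3
        rng = np.random.default_rng(21)
        frames = np.stack([base] * 4000)
        frames[:, 2, :] += rng.normal(0.0, sd, size=(4000, 3))
        fluct = rmsf(self.make_traj(frames), superpose=False)
        assert fluct[2] == pytest.approx(sd * np.sqrt(3.0), rel=0.05)
        assert np.max(np.delete(fluct, 2)) < 1e-10

    def test_requires_two_frames(self):
        traj = self.make_traj(build_helix(5).coordinates[None])
        with pytest.raises(ValueError, match="frames"):
            rmsf(traj)


class TestTrajectorySummary:
    def test_static_trajectory_has_zero_spread(self):
        base = build_helix(20).coordinates
        traj = TestRmsf.make_traj(np.stack([base] * 3))
        metrics = trajectory_summary(traj)
        assert metrics.rg_sd_A == 0.0
        assert metrics.rh_sd_A == 0.0
        assert metrics.rg_mean_A == pytest.approx(
            brute_force_rg(base, np.ones(20)), rel=1e-10)

    def test_volumes_share_the_sphere_formula(self):
        traj = TestRmsf.make_traj(build_helix(20).coordinates[None])
        metrics = trajectory_summary(traj)
        assert metrics.Vh_nm3 == volume_from_radius(metrics.rh_mean_A)
        assert metrics.Vg_nm3 == volume_from_radius(metrics.rg_mean_A)


class TestPdbIO:
    def test_single_model_round_trip(self, tmp_path):
        helix = build_helix(10)
        path = tmp_path / "helix.pdb"
        write_geometry_pdb(helix, path)
        traj = read_structure(path)
        assert traj.n_frames == 1
        assert traj.n_atoms == 10
        np.testing.assert_allclose(traj.frames[0], helix.coordinates, atol=1e-3)
        assert set(traj.elements) == {"C"}

    def test_multi_model_frames_in_order(self, tmp_path):
        base = build_helix(8).coordinates
        frames = np.stack([base + i * np.array([1.0, 0, 0]) for i in range(5)])
        traj = TestRmsf.make_traj(frames)
        path = tmp_path / "traj.pdb"
        write_pdb(traj, path)
        back = read_structure(path)
        assert back.n_frames == 5
        shifts = back.frames[:, 0, 0] - back.frames[0, 0, 0]
        np.testing.assert_allclose(shifts, np.arange(5), atol=1e-3)

    def test_masses_from_standard_table(self, tmp_path):
        helix = build_helix(4)
        path = tmp_path / "c.pdb"
        write_geometry_pdb(helix, path)
        traj = read_structure(path)
        np.testing.assert_allclose(traj.masses, 12.011)
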