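import numpy as np
import pytest

from compmd.errors import DegenerateGeometryError, InsufficientFramesError
from compmd.geometry import (
    angle_series,
    bfactor_from_rmsf,
    distance_series,
    kabsch_superpose,
    pearson_correlation,
    radius_of_gyration,
    rmsd_series,
    rmsf,
)
from compmd.synth import FixtureSpec, make_helix, make_two_state_ensemble
from compmd.traj_io import Trajectory


def quaternion_rmsd_oracle(p, q):
    """Independent superposed-RMSD via the quaternion (Horn) method."""
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    s = p.T @ q
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    e = (np.sum(p**2) + np.sum(q**2) - 2.0 * lam) / p.shape[0]
    return np.sqrt(max(e, 0.0))


def rigid_motion(coords, angle_deg, axis, translation):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    theta = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    rot = np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)
    return coords @ rot.T + np.asarray(translation)


class TestKabsch:
    def test_self_superposition_is_identity(self, helix10):
        coords = helix10.xyz[0]
        transform, result = kabsch_superpose(coords, coords)
        assert result.value == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_recovers_zero_rmsd(self, helix10):
        coords = helix10.xyz[0]
        moved = rigid_motion(coords, 37.0, [1, 2, 3], [5.0, -2.0, 1.0])
        _, result = kabsch_superpose(moved, coords)
        assert result.value < 1e-6

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(20):
            p = rng.normal(size=(7, 3)) * 3
            q = p + rng.normal(size=(7, 3)) * 0.5
            _, result = kabsch_superpose(p, q)
            assert result.value == pytest.approx(
                quaternion_rmsd_oracle(p, q), abs=1e-9)

    def test_rotation_is_proper_orthonormal(self, rng):
        p = rng.normal(size=(10, 3))
        q = rng.normal(size=(10, 3))
        transform, _ = kabsch_superpose(p, q)
        r = transform.rotation
        np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_reflection_branch_never_mirror_matches(self, rng):
        p = rng.normal(size=(6, 3))
        mirrored = p * np.array([-1.0, 1.0, 1.0])
        transform, _ = kabsch_superpose(mirrored, p)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0,
                                                                  abs=1e-9)

    def test_rmsd_invariant_links_value_and_deviations(self, rng):
        p = rng.normal(size=(9, 3))
        q = p + rng.normal(size=(9, 3))
        _, result = kabsch_superpose(p, q)
        assert result.value**2 * result.n_atoms == pytest.approx(
            np.sum(result.per_atom_deviation**2), rel=1e-9)

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line + 1.0)


class TestRmsdSeries:
    def test_identical_frames_give_zero(self, helix10):
        traj = Trajectory(topology=helix10.topology,
                          xyz=np.repeat(helix10.xyz, 5, axis=0))
        series = rmsd_series(traj, traj.frame(0))
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)

    def test_two_state_series_is_bimodal(self):
        ens = make_two_state_ensemble(FixtureSpec(
            seed=3, n_frames=80, noise_sigma=0.0, displacement=5.0))
        traj = ens.trajectory
        ground = np.flatnonzero(ens.state_labels == 0)[0]
        series = rmsd_series(traj, traj.frame(ground))
        on = series.values[ens.state_labels == 1]
        off = series.values[ens.state_labels == 0]
        assert np.allclose(off, 0.0, atol=1e-9)
        assert np.allclose(on, on[0], atol=1e-9)
        assert on[0] > 1.0

    def test_window_statistics_match_direct_recomputation(self,
                                                          two_state_small):
        traj = two_state_small.trajectory
        series = rmsd_series(traj, traj.frame(0),
                             equilibration_fraction=0.1)
        start = series.window[0]
        assert series.mean == pytest.approx(series.values[start:].mean())
        assert series.sd == pytest.approx(series.values[start:].std())

    def test_superposed_never_exceeds_unsuperposed(self, rng):
        p = rng.normal(size=(12, 3)) * 3
        q = p + rng.normal(size=(12, 3))
        _, result = kabsch_superpose(p, q)
        raw = np.sqrt(np.mean(np.sum((p - q) ** 2, axis=1)))
        assert result.value <= raw + 1e-12


class TestRmsf:
    def test_rigid_motion_only_gives_zero_rmsf(self, helix10):
        base = helix10.xyz[0]
        frames = np.stack([
            rigid_motion(base, a, [0, 0, 1], [a / 10, 0, 0])
            for a in (0.0, 15.0, 30.0, 45.0)])
        traj = Trajectory(topology=helix10.topology, xyz=frames)
        assert np.all(rmsf(traj) < 1e-6)

    def test_isotropic_noise_recovers_chi_moment(self):
        # RMSF of iid Gaussian noise (per coordinate sd σ) about the sample
        # mean is σ·sqrt(3)·sqrt((n−1)/n)
        sigma, n = 0.5, 2000
        helix = make_helix(24)
        rng = np.random.default_rng(77)
        xyz = helix.xyz[0][None] + rng.normal(
            0, sigma, size=(n, helix.n_atoms, 3))
        traj = Trajectory(topology=helix.topology, xyz=xyz)
        values = rmsf(traj)
        expected = sigma * np.sqrt(3.0) * np.sqrt((n - 1) / n)
        assert np.mean(values) == pytest.approx(expected, rel=0.05)

    def test_displaced_segment_fluctuates_more(self, two_state_small):
        traj = two_state_small.trajectory
        moved = two_state_small.displaced_atoms
        static = np.setdiff1d(np.arange(traj.n_atoms), moved)
        # fit on the static core so the jumping segment cannot drag the
        # reference frame
        values = rmsf(traj, fit_sel=static)
        assert values[moved].min() > values[static].max()

    def test_single_frame_rejected(self, helix10):
        with pytest.raises(InsufficientFramesError):
            rmsf(helix10)


class TestScalarDescriptors:
    def test_bfactor_closed_form(self):
        assert bfactor_from_rmsf(0.0) == 0.0
        assert bfactor_from_rmsf(1.0) == pytest.approx(26.3189, abs=1e-3)
        assert bfactor_from_rmsf(2.0) == pytest.approx(
            4 * bfactor_from_rmsf(1.0))
        with pytest.raises(ValueError):
            bfactor_from_rmsf(-0.1)

    def test_rg_two_point_and_ring(self):
        pair = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        assert radius_of_gyration(pair) == pytest.approx(2.0)
        theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        ring = np.column_stack([7 * np.cos(theta), 7 * np.sin(theta),
                                np.zeros_like(theta)])
        assert radius_of_gyration(ring) == pytest.approx(7.0, rel=0.01)
        shifted = radius_of_gyration(ring + np.array([10.0, -3.0, 2.0]))
        assert shifted == pytest.approx(radius_of_gyration(ring), abs=1e-9)

    def test_distance_and_angle_series(self):
        helix = make_helix(2)
        xyz = np.array([[[0.0, 0, 0], [3.0, 4.0, 0], [6.0, 0, 0],
                         [0.0, 1.0, 0], [1.0, 0, 0], [1.0, 1.0, 0],
                         [9.0, 9, 9], [8, 8, 8]]])
        traj = Trajectory(topology=helix.topology, xyz=xyz)
        assert distance_series(traj, 0, 1)[0] == pytest.approx(5.0)
        assert angle_series(traj, 0, 4, 5)[0] == pytest.approx(90.0)
        assert angle_series(traj, 0, 4, 2)[0] == pytest.approx(180.0)
        with pytest.raises(ValueError):
            distance_series(traj, 2, 2)

    def test_pearson_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert pearson_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        # direct-formula oracle
        r = (np.sum((x - x.mean()) * (y - y.mean()))
             / np.sqrt(np.sum((x - x.mean())**2) * np.sum((y - y.mean())**2)))
        assert pearson_correlation(x, y) == pytest.approx(r, abs=1e-12)
        with pytest.raises(ValueError):
            pearson_correlation(x, np.full(5, 2.0))
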