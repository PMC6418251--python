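"""Superposition, RMSD/L-RMSD, distance series, occupancy and replica stats."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.spatial.transform import Rotation

from epistat.errors import DegenerateGeometryError, EmptyWindowError, UsageError
from epistat.structures import ContactDefinition, ca_mask, representative_distance
from epistat.synthetic_data import TrajectorySpec, make_synthetic_trajectory, \
    make_toy_complex
from epistat.trajectory import (
    Trajectory,
    contact_occupancy,
    distance_series,
    kabsch_superpose,
    lrmsd_series,
    replica_summary,
    rmsd_series,
)


def quaternion_rmsd(mobile, reference):
    """Independent minimal-RMSD via Horn's quaternion method (largest
    eigenvalue of the 4x4 key matrix)."""
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)
    s = a.T @ b
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key).max()
    g = float((a ** 2).sum() + (b ** 2).sum())
    return math.sqrt(max(0.0, g - 2.0 * lam) / len(a))


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        res = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(res.translation, 0.0, atol=1e-12)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_rotation(self, rng):
        pts = rng.normal(size=(25, 3))
        rot0 = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-5, 5, 3)
        moved = pts @ rot0.T + shift
        res = kabsch_superpose(moved, pts)  # maps moved back onto pts
        np.testing.assert_allclose(res.rotation, rot0.T, atol=1e-9)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.apply(moved), pts, atol=1e-9)

    def test_rotation_is_proper_orthonormal(self, rng):
        a, b = rng.normal(size=(30, 3)), rng.normal(size=(30, 3))
        res = kabsch_superpose(a, b)
        np.testing.assert_allclose(res.rotation.T @ res.rotation, np.eye(3),
                                   atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_oracle(self, rng):
        ref = rng.normal(scale=5.0, size=(50, 3))
        mobile = ref + rng.normal(scale=0.5, size=(50, 3))
        res = kabsch_superpose(mobile, ref)
        assert res.rmsd == pytest.approx(quaternion_rmsd(mobile, ref), abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(6.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)

    @settings(max_examples=25, derandomize=True)
    @given(hst.integers(0, 2 ** 31 - 1))
    def test_fitted_rmsd_never_exceeds_unfitted(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(scale=3.0, size=(12, 3))
        b = rng.normal(scale=3.0, size=(12, 3))
        unfitted = math.sqrt(float(np.mean(np.sum((a - b) ** 2, axis=1))))
        assert kabsch_superpose(a, b).rmsd <= unfitted + 1e-12


def _static_traj(model, n_frames=5, dt=0.01):
    coords = model.coords()
    frames = np.repeat(coords[None], n_frames, axis=0)
    return Trajectory(topology=model, frames=frames,
                      times=np.arange(n_frames) * dt)


class TestRmsdSeries:
    def test_static_trajectory_is_zero(self, planted_toy):
        traj = _static_traj(planted_toy)
        mask = ca_mask(planted_toy, ["A", "B"], 0)
        series = rmsd_series(traj, mask, planted_toy)
        np.testing.assert_allclose(series[:, 1], 0.0, atol=1e-12)

    def test_per_frame_rigid_motion_removed(self, planted_toy, rng):
        coords = planted_toy.coords()
        frames = np.stack([
            coords @ Rotation.random(rng=rng).as_matrix().T
            + rng.uniform(-20, 20, 3)
            for _ in range(8)
        ])
        traj = Trajectory(planted_toy, frames, np.arange(8) * 0.01)
        mask = ca_mask(planted_toy, ["A", "B"], 0)
        series = rmsd_series(traj, mask, planted_toy)
        np.testing.assert_allclose(series[:, 1], 0.0, atol=1e-9)

    def test_gaussian_noise_gives_sigma_sqrt3(self, rng):
        # isotropic jitter sigma per coordinate -> RMSD ~= sigma * sqrt(3)
        sigma = 0.4
        n_atoms, n_frames = 120, 1000
        coords = rng.uniform(0, 30, (n_atoms, 3))
        from conftest import build_model
        model = build_model({("A", i + 1, "ALA"): {"CA": coords[i]}
                             for i in range(n_atoms)})
        frames = coords[None] + rng.normal(0, sigma, (n_frames, n_atoms, 3))
        traj = Trajectory(model, frames, np.arange(n_frames) * 0.01)
        series = rmsd_series(traj, np.arange(n_atoms), model)
        assert series[:, 1].mean() == pytest.approx(sigma * math.sqrt(3), rel=0.05)


class TestLrmsd:
    def test_whole_complex_rigid_motion_is_zero(self, planted_toy, rng):
        coords = planted_toy.coords()
        frames = np.stack([
            coords @ Rotation.random(rng=rng).as_matrix().T + rng.uniform(-9, 9, 3)
            for _ in range(6)
        ])
        traj = Trajectory(planted_toy, frames, np.arange(6) * 0.01)
        fit = ca_mask(planted_toy, ["A"], 0)
        measure = ca_mask(planted_toy, ["B"], 0)
        res = lrmsd_series(traj, fit, measure, planted_toy)
        np.testing.assert_allclose(res.series[:, 1], 0.0, atol=1e-9)

    def test_pure_antibody_translation_gives_exact_displacement(self, planted_toy):
        coords = planted_toy.coords()
        moved = coords.copy()
        b_idx = [i for i, (k, _) in enumerate(planted_toy.atoms())
                 if k.chain_id == "B"]
        moved[b_idx] += np.array([3.0, 0.0, 0.0])
        traj = Trajectory(planted_toy, np.stack([coords, moved]),
                          np.array([0.0, 0.01]))
        fit = ca_mask(planted_toy, ["A"], 0)
        measure = ca_mask(planted_toy, ["B"], 0)
        res = lrmsd_series(traj, fit, measure, planted_toy)
        assert res.series[1, 1] == pytest.approx(3.0, abs=1e-9)

    def test_overlapping_masks_rejected(self, planted_toy):
        mask = ca_mask(planted_toy, ["A"], 0)
        traj = _static_traj(planted_toy)
        with pytest.raises(UsageError):
            lrmsd_series(traj, mask, mask, planted_toy)

    def test_drift_trajectory_increases_and_reaches_planted_displacement(self):
        model = make_toy_complex(8, 8, [], seed=5)
        spec = TrajectorySpec(reference=model, jitter_sd=0.05, drift_chain="B",
                              drift_a_per_ns=0.1, n_frames=1001, dt_ns=0.1,
                              seed=9)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # large drift triggers the imaging warning
            traj, _ = make_synthetic_trajectory(spec)
        fit = ca_mask(model, ["A"], 0)
        measure = ca_mask(model, ["B"], 0)
        res = lrmsd_series(traj, fit, measure, model)
        values = res.series[:, 1]
        # increasing trend after burn-in: the fitted slope recovers the
        # drift velocity and every quarter-window mean exceeds the last
        post_mask = res.series[:, 0] >= 20.0
        post_t, post = res.series[post_mask, 0], values[post_mask]
        slope = np.polyfit(post_t, post, 1)[0]
        assert slope == pytest.approx(0.1, rel=0.05)
        quarters = np.array_split(post, 4)
        q_means = [q.mean() for q in quarters]
        assert all(a < b for a, b in zip(q_means, q_means[1:]))
        assert values[-1] == pytest.approx(10.0, abs=0.2)


class TestDistanceSeries:
    def test_static_equals_crystal_distance(self, planted_toy):
        ka = planted_toy.find_residue("A", 10)
        kb = planted_toy.find_residue("B", 20)
        contact = ContactDefinition("K-D", ka, kb, "NZ", "CG", threshold=3.6)
        traj = _static_traj(planted_toy, n_frames=4)
        series = distance_series(traj, contact)
        np.testing.assert_allclose(series[:, 1], 3.6, atol=1e-12)

    def test_reproduces_constructed_oscillation(self):
        from conftest import build_model
        model = build_model({
            ("A", 1, "LYS"): {"NZ": (0, 0, 0)},
            ("B", 2, "ASP"): {"CG": (0, 0, 4.0)},
        })
        t = np.linspace(0, 2 * np.pi, 50)
        coords = model.coords()
        frames = np.repeat(coords[None], 50, axis=0)
        frames[:, 1, 2] = 4.0 + np.sin(t)
        traj = Trajectory(model, frames, np.arange(50) * 0.01)
        contact = ContactDefinition("K-D", model.find_residue("A", 1),
                                    model.find_residue("B", 2), "NZ", "CG", 4.0)
        series = distance_series(traj, contact)
        np.testing.assert_allclose(series[:, 1], 4.0 + np.sin(t), atol=1e-9)

    def test_agrees_with_representative_distance_per_frame(self, planted_toy, rng):
        coords = planted_toy.coords()
        frames = coords[None] + rng.normal(0, 0.5, (6, *coords.shape))
        traj = Trajectory(planted_toy, frames, np.arange(6) * 0.01)
        ka = planted_toy.find_residue("A", 10)
        kb = planted_toy.find_residue("B", 20)
        contact = ContactDefinition("K-D", ka, kb, "NZ", "CG", threshold=3.6)
        series = distance_series(traj, contact)
        for i in range(6):
            frame_model = planted_toy.with_coords(frames[i])
            expect = representative_distance(frame_model,
                                             frame_model.find_residue("A", 10),
                                             frame_model.find_residue("B", 20))
            assert series[i, 1] == pytest.approx(expect, abs=1e-9)


class TestOccupancy:
    def test_counting_with_burn_in(self):
        series = np.array([[30.0, 3.0], [50.0, 5.0], [70.0, 3.0], [90.0, 5.0]])
        assert contact_occupancy(series, threshold=4.0, burn_in=20.0) == 0.5

    def test_all_below_threshold(self):
        series = np.column_stack([np.arange(10.0), np.full(10, 2.0)])
        assert contact_occupancy(series, threshold=3.0) == 1.0

    def test_exact_planted_fraction(self):
        n = 1000
        inside = np.zeros(n, dtype=bool)
        inside[:763] = True
        rng = np.random.default_rng(4)
        rng.shuffle(inside)
        series = np.column_stack([np.arange(n, dtype=float),
                                  np.where(inside, 3.0, 5.0)])
        assert contact_occupancy(series, threshold=4.0) == pytest.approx(0.763)

    def test_empty_window_rejected(self):
        series = np.array([[1.0, 3.0], [2.0, 3.0]])
        with pytest.raises(EmptyWindowError):
            contact_occupancy(series, threshold=4.0, burn_in=10.0)

    @settings(max_examples=25, derandomize=True)
    @given(hst.integers(0, 2 ** 31 - 1))
    def test_frame_order_invariant_and_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        series = np.column_stack([np.arange(n, dtype=float),
                                  rng.uniform(2.0, 6.0, n)])
        perm = rng.permutation(n)
        shuffled = series[perm]
        # reassign times so the permuted series is still a valid series
        shuffled = np.column_stack([np.arange(n, dtype=float), shuffled[:, 1]])
        occ = [contact_occupancy(series, thr) for thr in (3.0, 4.0, 5.0)]
        occ_shuffled = [contact_occupancy(shuffled, thr) for thr in (3.0, 4.0, 5.0)]
        assert occ == occ_shuffled
        assert occ[0] <= occ[1] <= occ[2]


class TestReplicaSummary:
    def test_constant_replicas(self):
        res = replica_summary([0.5, 0.5, 0.5])
        assert res.mean == 0.5 and res.sd == 0.0 and res.se == 0.0

    def test_reported_triple_hand_computation(self):
        # across-run occupancies 77.3%, 83.3%, 26.7% -> mean 62.4%, sd 31.1%
        res = replica_summary([0.773, 0.833, 0.267])
        assert res.mean == pytest.approx(0.624, abs=5e-4)
        assert res.sd == pytest.approx(0.311, abs=5e-4)
        assert res.se == pytest.approx(res.sd / math.sqrt(3))

    def test_permutation_invariance(self):
        a = replica_summary([0.1, 0.7, 0.4])
        b = replica_summary([0.7, 0.4, 0.1])
        assert (a.mean, a.sd, a.se) == (b.mean, b.sd, b.se)

    def test_single_replica_flags_undefined_spread(self):
        res = replica_summary([0.8])
        assert res.mean == 0.8 and not res.spread_defined
        assert math.isnan(res.sd) and math.isnan(res.se)
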