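"""Synthetic phantoms and the virtual validation experiments."""

import numpy as np
import pytest

from arguide.mesh import MeshQuery
from arguide.phantom import (Phantom, PhantomSpec, PlacementNoise, TrackingNoise,
                             default_phantom_specs, generate_phantom, placement_trial,
                             run_experiment, tracking_trial, trials_to_dataframe)
from arguide.transforms import RigidTransform, rotation_from_axis_angle


class TestGeneratePhantom:
    def test_deterministic_same_seed(self):
        spec = PhantomSpec("T", (80.0, 60.0, 50.0), seed=3, pitch_mm=2.0)
        a = generate_phantom(spec)
        b = generate_phantom(spec)
        assert np.array_equal(a.bone.vertices, b.bone.vertices)
        assert np.array_equal(a.fiducials.points, b.fiducials.points)
        assert np.array_equal(a.guide.body.vertices, b.guide.body.vertices)

    def test_different_seed_differs(self):
        a = generate_phantom(PhantomSpec("T", (80.0, 60.0, 50.0), seed=1, pitch_mm=2.0))
        b = generate_phantom(PhantomSpec("T", (80.0, 60.0, 50.0), seed=2, pitch_mm=2.0))
        assert not np.array_equal(a.fiducials.points, b.fiducials.points)

    def test_bounding_box_within_spec(self, stock_phantoms):
        for ph in stock_phantoms:
            assert (ph.body.extents() <= np.asarray(ph.spec.dims_mm) + 1e-6).all()

    def test_meshes_watertight(self, small_phantom):
        for m in (small_phantom.bone, small_phantom.tumor, small_phantom.support,
                  small_phantom.body, small_phantom.guide.body):
            assert m.is_watertight()

    def test_eight_fiducials_on_surface(self, stock_phantoms):
        for ph in stock_phantoms:
            assert len(ph.fiducials) == 8
            d, _, _, _ = ph.bone_query().closest(ph.fiducials.points)
            assert d.max() < 0.1

    def test_guide_fiducial_counts(self, stock_phantoms):
        for ph in stock_phantoms:
            assert 3 <= len(ph.guide.fiducial_cones) <= 5
            for _, _, dia, dep in ph.guide.fiducial_cones:
                assert dia == 4.0 and dep == 3.0

    def test_stability_com_over_base(self, stock_phantoms):
        for ph in stock_phantoms:
            com = ph.body.solid_centroid()
            lo, hi = ph.support.bounds()
            assert lo[0] <= com[0] <= hi[0] and lo[1] <= com[1] <= hi[1]

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec("T", (0.0, 10.0, 10.0))
        with pytest.raises(ValueError):
            PhantomSpec("T", (50.0, 50.0, 50.0), n_guide_fiducials=6)


class TestPlacementTrial:
    def test_noiseless_chain_exact(self, small_phantom):
        t = placement_trial(small_phantom, PlacementNoise.zero(), seed=5)
        assert t.errors_mm.max() < 1e-6
        assert t.fre_mm < 1e-9

    def test_error_count_matches_guide_fiducials(self, small_phantom):
        t = placement_trial(small_phantom, PlacementNoise(), seed=5)
        assert len(t.errors_mm) == len(small_phantom.guide.fiducial_cones)

    def test_localization_noise_monte_carlo(self, small_phantom):
        """Localization-only noise: mean error matches a direct re-simulation."""
        noise = PlacementNoise(0.0, 0.0, 0.5)
        errs = np.concatenate([
            placement_trial(small_phantom, noise, seed=s).errors_mm for s in range(300)
        ])
        errs2 = np.concatenate([
            placement_trial(small_phantom, noise, seed=s).errors_mm
            for s in range(10_000, 10_300)
        ])
        assert abs(errs.mean() - errs2.mean()) / errs2.mean() < 0.05


class TestTrackingTrial:
    def test_noiseless_exact(self, small_phantom):
        t = tracking_trial(small_phantom, noise=TrackingNoise.zero(), seed=5)
        assert t.errors_mm.max() < 1e-6

    def test_fourteen_targets(self, small_phantom):
        t = tracking_trial(small_phantom, noise=TrackingNoise(), seed=5)
        assert len(t.errors_mm) == 14
        assert len(t.distance_to_marker_mm) == 14

    def test_rotation_noise_lever_arm(self, small_phantom):
        """Rotational marker noise only: error grows with distance to marker."""
        from scipy import stats

        noise = TrackingNoise(0.0, 0.5, 0.0, 0.0, 0.0)
        d, e = [], []
        for s in range(80):
            t = tracking_trial(small_phantom, noise=noise, n_targets=14, seed=s)
            d.extend(t.distance_to_marker_mm)
            e.extend(t.errors_mm)
        rho, p = stats.spearmanr(d, e)
        assert rho > 0 and p < 1e-4

    def test_tracking_dominates_placement_only_error(self, small_phantom):
        """Adding marker-pose noise strictly inflates the mean error."""
        base = TrackingNoise(0.0, 0.0, 0.5, 0.5, 0.0)
        full = TrackingNoise(0.5, 0.5, 0.5, 0.5, 0.0)
        m_base = np.mean([tracking_trial(small_phantom, noise=base, seed=s).errors_mm.mean()
                          for s in range(100)])
        m_full = np.mean([tracking_trial(small_phantom, noise=full, seed=s).errors_mm.mean()
                          for s in range(100)])
        assert m_full > m_base


class TestRunExperiment:
    def test_factorial_counts_and_balance(self, stock_phantoms):
        trials = run_experiment(stock_phantoms, users=2, reps=5,
                                noise=PlacementNoise(), kind="placement", seed=4)
        assert len(trials) == 60  # 6 phantoms x 2 users x 5 reps
        per_user = {u: sum(1 for t in trials if t.user == u) for u in (1, 2)}
        assert per_user[1] == per_user[2] == 30

    def test_reproducible_from_master_seed(self, small_phantom):
        a = run_experiment([small_phantom], users=2, reps=2, kind="tracking", seed=9)
        b = run_experiment([small_phantom], users=2, reps=2, kind="tracking", seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.errors_mm, y.errors_mm)

    def test_world_pose_invariance(self, small_phantom, monkeypatch):
        """Error distributions do not depend on where the phantom sits in
        the world frame (distances are rigid-motion invariant)."""
        import arguide.phantom as P
        from arguide.transforms import compose, random_rigid

        ref = [tracking_trial(small_phantom, noise=TrackingNoise(), seed=s).errors_mm.mean()
               for s in range(150)]
        extra = RigidTransform(rotation_from_axis_angle([1, 2, 3], 1.1),
                               np.array([500.0, -200.0, 300.0]), "world", "world")
        orig = P.random_rigid
        monkeypatch.setattr(P, "random_rigid",
                            lambda rng, mt, parent="world", child="anatomy":
                            compose(extra, orig(rng, mt, "world", child)))
        moved = [tracking_trial(small_phantom, noise=TrackingNoise(), seed=s).errors_mm.mean()
                 for s in range(150)]
        assert abs(np.mean(ref) - np.mean(moved)) / np.mean(ref) < 0.10


def test_trials_dataframe_columns(small_phantom):
    trials = run_experiment([small_phantom], users=2, reps=2, kind="tracking", seed=1)
    df = trials_to_dataframe(trials)
    assert set(df.columns) == {"case", "user", "rep", "kind", "target",
                               "error_mm", "distance_to_marker_mm"}
    assert len(df) == 2 * 2 * 14
    assert (df.error_mm >= 0).all()
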