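"""Landmarks, CSV persistence, rigid fitting, and volume resampling."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from voxscene import (
    ImageVolume,
    LandmarkSet,
    RigidTransform,
    apply_rigid_resample,
    fit_rigid,
    fit_rigid_landmarks,
    load_landmarks,
    rms_residual,
    save_landmarks,
)
from voxscene.errors import (
    DegenerateConfigurationError,
    LandmarkParseError,
    NameCollisionError,
)
from voxscene.fixtures import make_two_pose_landmarks


def _random_rigid(rng):
    R = Rotation.random(random_state=np.random.RandomState(int(rng.integers(2**31)))).as_matrix()
    return RigidTransform(R, rng.uniform(-20, 20, 3))


class TestLandmarkSet:
    def test_add_then_remove_leaves_empty_set(self):
        s = LandmarkSet("c")
        s.add("a", (1, 2, 3))
        s.remove("a")
        assert len(s) == 0

    def test_duplicate_add_rejected(self):
        s = LandmarkSet("c")
        s.add("a", (0, 0, 0))
        with pytest.raises(NameCollisionError):
            s.add("a", (1, 1, 1))

    def test_rename_preserves_position_and_color(self):
        s = LandmarkSet("c")
        s.add("a", (1, 2, 3), color=(0, 0, 1))
        s.rename("a", "b")
        m = s.get("b")
        assert np.array_equal(m.position, [1, 2, 3])
        assert m.color == (0, 0, 1)
        assert "a" not in s


class TestLandmarkIO:
    def test_round_trip_of_five_landmarks(self, tmp_path, rng):
        s = LandmarkSet("c")
        for k in range(5):
            s.add(f"p{k}", rng.uniform(-100, 100, 3), color=tuple(rng.random(3).round(3)))
        p = tmp_path / "marks.csv"
        save_landmarks(s, p)
        back = load_landmarks(p)
        assert back.names() == s.names()
        assert np.allclose(back.positions(), s.positions(), atol=1e-6)
        for n in s.names():
            assert np.allclose(back.get(n).color, s.get(n).color, atol=1e-6)

    def test_empty_set_round_trips(self, tmp_path):
        p = tmp_path / "empty.csv"
        save_landmarks(LandmarkSet("c"), p)
        assert len(load_landmarks(p)) == 0

    def test_wrong_column_count_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("name,x,y,z,r,g,b\nok,1,2,3,1,0,0\nbad,1,2\n")
        with pytest.raises(LandmarkParseError) as exc:
            load_landmarks(p)
        assert exc.value.line == 3


class TestFitRigid:
    def test_identity_when_dst_equals_src(self, rng):
        pts = rng.random((6, 3)) * 10
        t = fit_rigid(pts, pts)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0, atol=1e-12)

    def test_recovers_known_rigid_to_1e9(self, rng):
        t0 = _random_rigid(rng)
        src = rng.uniform(0, 100, (10, 3))
        t = fit_rigid(src, t0.apply(src))
        assert np.abs(t.rotation - t0.rotation).max() < 1e-9
        assert np.abs(t.translation - t0.translation).max() < 1e-9

    def test_agrees_with_scipy_align_vectors(self, rng):
        """Independent cross-check: scipy's Wahba solver on the centered
        points must give the same rotation for noisy correspondences."""
        t0 = _random_rigid(rng)
        src = rng.uniform(0, 50, (12, 3))
        dst = t0.apply(src) + rng.normal(0, 0.5, (12, 3))
        t = fit_rigid(src, dst)
        ref, _ = Rotation.align_vectors(dst - dst.mean(0), src - src.mean(0))
        assert np.allclose(t.rotation, ref.as_matrix(), atol=1e-8)

    def test_planar_case_matches_brute_force_angle_search(self, rng):
        angle = 33.7519
        R = RigidTransform.from_axis_angle((0, 0, 1), angle)
        src = np.column_stack([rng.uniform(0, 10, 8), rng.uniform(0, 10, 8), np.zeros(8)])
        dst = R.apply(src) + np.array([2.0, -1.0, 0.0])
        fitted = fit_rigid(src, dst)
        rec = np.rad2deg(np.arctan2(fitted.rotation[1, 0], fitted.rotation[0, 0]))

        # brute force: scan candidate in-plane angles on a 0.001° grid and
        # evaluate the centered least-squares cost directly
        sc = src - src.mean(0)
        dc = dst - dst.mean(0)
        dots = (sc[:, 0] * dc[:, 0] + sc[:, 1] * dc[:, 1]).sum()
        crosses = (sc[:, 0] * dc[:, 1] - sc[:, 1] * dc[:, 0]).sum()
        grid = np.arange(0, 360, 0.001)
        rad = np.deg2rad(grid)
        cost = -(np.cos(rad) * dots + np.sin(rad) * crosses)
        best = grid[np.argmin(cost)]
        assert abs(((rec - best) + 180) % 360 - 180) <= 0.001

    def test_degenerate_configurations_rejected(self, rng):
        with pytest.raises(DegenerateConfigurationError):
            fit_rigid(rng.random((2, 3)), rng.random((2, 3)))
        line = np.outer(np.arange(5), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateConfigurationError):
            fit_rigid(line, line)

    def test_invariant_under_common_rigid_motion(self, rng):
        t0 = _random_rigid(rng)
        motion = _random_rigid(rng)
        src = rng.uniform(0, 50, (8, 3))
        dst = t0.apply(src) + rng.normal(0, 0.3, (8, 3))
        res1 = rms_residual(fit_rigid(src, dst), src, dst)
        src2, dst2 = motion.apply(src), motion.apply(dst)
        res2 = rms_residual(fit_rigid(src2, dst2), src2, dst2)
        assert res1 == pytest.approx(res2, abs=1e-9)

    def test_with_scale_recovers_similarity(self, rng):
        t0 = _random_rigid(rng)
        scale0 = 1.7
        src = rng.uniform(0, 50, (10, 3))
        dst = scale0 * src @ t0.rotation.T + t0.translation
        t, scale = fit_rigid(src, dst, with_scale=True)
        assert scale == pytest.approx(scale0, abs=1e-9)
        assert np.abs(t.rotation - t0.rotation).max() < 1e-9


class TestHomonymousPairing:
    def test_pairs_by_name_and_ignores_unpaired(self, rng):
        t0 = _random_rigid(rng)
        a, b = make_two_pose_landmarks(8, t0, noise_sigma=0.0, rng_seed=3)
        a.add("only-in-a", (0, 0, 0))
        t = fit_rigid_landmarks(a, b)
        assert np.abs(t.rotation - t0.rotation).max() < 1e-9

    def test_no_common_names_rejected(self):
        a = LandmarkSet("a")
        b = LandmarkSet("b")
        for k in range(3):
            a.add(f"a{k}", (k, 0, 0))
            b.add(f"b{k}", (k, 0, 0))
        with pytest.raises(DegenerateConfigurationError):
            fit_rigid_landmarks(a, b)


class TestRMSResidual:
    def test_perfect_fit_is_zero(self, rng):
        t0 = _random_rigid(rng)
        src = rng.random((5, 3))
        assert rms_residual(t0, src, t0.apply(src)) == 0

    def test_single_pair_unit_distance(self):
        t = RigidTransform.identity()
        assert rms_residual(t, [[0, 0, 0]], [[1, 0, 0]]) == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng):
        t = _random_rigid(rng)
        src, dst = rng.random((9, 3)), rng.random((9, 3))
        direct = np.sqrt(np.mean(np.sum((t.apply(src) - dst) ** 2, axis=1)))
        assert rms_residual(t, src, dst) == pytest.approx(direct)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rms_residual(RigidTransform.identity(), np.zeros((2, 3)), np.zeros((3, 3)))


class TestResampling:
    def test_identity_transform_is_bitwise(self, random_volume):
        out = apply_rigid_resample(random_volume, RigidTransform.identity())
        assert np.array_equal(out.data, random_volume.data)

    def test_integer_voxel_translation_shifts_exactly(self, rng):
        data = rng.integers(0, 256, (4, 5, 6), dtype=np.uint8).astype(np.uint8)
        vol = ImageVolume(data, calibration=(2.0, 1.0, 1.0))
        t = RigidTransform(np.eye(3), (2 * 2.0, 0.0, 0.0))  # +2 voxels in x
        out = apply_rigid_resample(vol, t)
        expected = np.zeros_like(data)
        expected[:, :, 2:] = data[:, :, :-2]
        assert np.array_equal(out.data, expected)

    def test_90_degree_rotation_equals_grid_permutation(self, rng):
        n = 8
        data = rng.integers(0, 256, (n, n, n), dtype=np.uint8).astype(np.uint8)
        vol = ImageVolume(data)
        t = RigidTransform.from_axis_angle((0, 0, 1), 90.0, center=(n / 2, n / 2, n / 2))
        out = apply_rigid_resample(vol, t)
        assert np.array_equal(out.data, np.rot90(data, k=-1, axes=(1, 2)))

    def test_forward_then_inverse_close_on_smooth_phantom(self):
        # compact smooth blob: rotations keep it inside the grid, so the
        # only error left is interpolation blur
        from scipy import ndimage

        from voxscene.fixtures import make_sphere_volume

        raw = make_sphere_volume((24, 24, 24), radius=7).data.astype(float)
        blurred = ndimage.gaussian_filter(raw, sigma=2.0)
        vol = ImageVolume(np.clip(blurred, 0, 255).astype(np.uint8))
        t = RigidTransform.from_axis_angle((1, 1, 0), 23.0, center=(12, 12, 12))
        there = apply_rigid_resample(vol, t)
        back = apply_rigid_resample(there, t.inverse())
        mae = np.abs(back.data.astype(float) - vol.data.astype(float)).mean()
        assert mae / 255.0 < 0.02
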