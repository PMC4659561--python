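import numpy as np
import pytest

from filmgaze import (
    FrameGaze,
    density_at,
    cross_condition_similarity,
    loo_gaze_similarity,
    shot_mean_similarity,
    shuffled_baseline,
)
from filmgaze.gaze_io import ShotIndex
from filmgaze.synchrony import SimilarityResult, NormalizationConstants, shuffle_frame_gaze

from .conftest import make_frame_gaze, random_frame_gaze
from .oracles import brute_cross_similarity, brute_loo_similarity


class TestDensityAt:
    def test_unit_height_kernel_at_own_center(self, geometry):
        p = np.array([[300.0, 200.0]])
        assert density_at(p, (300.0, 200.0), 1.2, geometry) == pytest.approx(1.0)

    def test_additivity_of_coincident_points(self, geometry):
        p = np.array([[300.0, 200.0], [300.0, 200.0]])
        assert density_at(p, (300.0, 200.0), 1.2, geometry) == pytest.approx(2.0)

    def test_empty_point_set_gives_zero(self, geometry):
        assert density_at(np.empty((0, 2)), (10.0, 10.0), 1.2, geometry) == 0.0

    def test_matches_three_term_brute_force(self, geometry):
        pts = np.array([[100.0, 80.0], [350.0, 260.0], [600.0, 420.0]])
        q = (333.0, 111.0)
        expected = sum(
            np.exp(
                -(
                    ((q[0] - x) / geometry.px_per_deg_x) ** 2
                    + ((q[1] - y) / geometry.px_per_deg_y) ** 2
                )
                / (2 * 1.2**2)
            )
            for x, y in pts
        )
        assert density_at(pts, q, 1.2, geometry) == pytest.approx(expected, abs=1e-12)


class TestBruteForceEquivalence:
    """Full pipeline vs an independent double-loop implementation (<=4 viewers, <=5 frames)."""

    @pytest.mark.parametrize("population", ["grid", "samples"])
    @pytest.mark.parametrize("seed,n_p,n_f", [(0, 3, 2), (1, 4, 5), (2, 2, 4)])
    def test_loo_matches_oracle(self, geometry, population, seed, n_p, n_f):
        fg = random_frame_gaze(geometry, n_p, n_f, seed)
        res = loo_gaze_similarity(
            fg, grid_stride_px=60, normalization_population=population
        )
        raw, z, mean, sd = brute_loo_similarity(
            fg, grid_stride_px=60, population=population
        )
        np.testing.assert_allclose(res.raw, raw, atol=1e-9)
        np.testing.assert_allclose(res.constants.mean, mean, atol=1e-9)
        np.testing.assert_allclose(res.constants.sd, sd, atol=1e-9)
        np.testing.assert_allclose(res.z, z, atol=1e-9)

    @pytest.mark.parametrize("population", ["grid", "samples"])
    def test_cross_matches_oracle(self, geometry, population):
        fg_a = random_frame_gaze(geometry, 2, 5, seed=11)
        fg_r = random_frame_gaze(geometry, 3, 5, seed=12)
        res = cross_condition_similarity(
            fg_a, fg_r, grid_stride_px=60, normalization_population=population
        )
        raw, z, mean, sd = brute_cross_similarity(
            fg_a, fg_r, grid_stride_px=60, population=population
        )
        np.testing.assert_allclose(res.raw, raw, atol=1e-9)
        np.testing.assert_allclose(res.z, z, atol=1e-9)


class TestLeaveOneOut:
    def test_static_identical_gaze_flagged_undefined(self, geometry):
        # every viewer on the same point for the whole video: raw values are
        # constant, their SD is 0 and the z-score is undefined
        x = np.full((3, 5), 100.0)
        y = np.full((3, 5), 150.0)
        valid = np.ones((3, 5), bool)
        fg = FrameGaze(geometry, ["a", "b", "c"], x, y, valid)
        with pytest.warns(UserWarning, match="degenerate"):
            res = loo_gaze_similarity(
                fg, window_ms=30, grid_stride_px=60, normalization_population="samples"
            )
        assert res.undefined
        assert np.isnan(res.z).all()  # no silent zeros

    @pytest.mark.parametrize("population", ["grid", "samples"])
    def test_z_invariant_under_kernel_scaling(self, geometry, population):
        fg = random_frame_gaze(geometry, 4, 4, seed=5)
        kw = dict(grid_stride_px=60, normalization_population=population)
        res1 = loo_gaze_similarity(fg, kernel_scale=1.0, **kw)
        res2 = loo_gaze_similarity(fg, kernel_scale=7.5, **kw)
        np.testing.assert_allclose(res1.z, res2.z, atol=1e-9)

    def test_z_only_defined_at_valid_frames(self, geometry):
        fg = random_frame_gaze(geometry, 3, 6, seed=8, p_valid=0.5)
        res = loo_gaze_similarity(fg, grid_stride_px=60)
        assert np.array_equal(np.isfinite(res.z), fg.valid)

    def test_needs_two_participants(self, geometry):
        fg = random_frame_gaze(geometry, 1, 3, seed=0)
        with pytest.raises(ValueError):
            loo_gaze_similarity(fg)

    def test_sample_pooled_z_is_centred(self):
        """Pooled mean of leave-one-out z over the video is ~0 under sample pooling."""
        fg = make_frame_gaze(sigma_deg=2.0, seed=4, n_viewers=6)
        res = loo_gaze_similarity(
            fg, grid_stride_px=24, normalization_population="samples"
        )
        assert abs(np.nanmean(res.z)) < 0.15


class TestCrossCondition:
    def test_identical_conditions_fluctuate_identically(self):
        """Scoring a condition against itself reproduces its own similarity dynamics.

        The raw cross-condition value differs from the leave-one-out value by
        exactly the viewer's own kernel contribution: at least 1 (their own
        gaze point at the scored frame) and at most the window size in
        unit-height kernels.  The z time-courses therefore co-fluctuate.
        """
        fg = make_frame_gaze(sigma_deg=2.0, seed=9, n_viewers=6)
        loo = loo_gaze_similarity(fg, grid_stride_px=24)
        cross = cross_condition_similarity(fg, fg, grid_stride_px=24)
        diff = cross.raw - loo.raw
        defined = np.isfinite(diff)
        window_frames = 7  # 225 ms at 30 fps
        assert (diff[defined] >= 1.0 - 1e-9).all()
        assert (diff[defined] <= window_frames + 1e-9).all()
        assert np.corrcoef(loo.mean_timecourse(), cross.mean_timecourse())[0, 1] > 0.9

    def test_disjoint_support_gives_strongly_negative_z(self, geometry):
        fg_ref = make_frame_gaze(sigma_deg=1.0, seed=2, n_viewers=6)
        far = FrameGaze(
            geometry,
            list(fg_ref.participants),
            fg_ref.x + 3 * geometry.width_px,
            fg_ref.y.copy(),
            fg_ref.valid.copy(),
        )
        res = cross_condition_similarity(
            far, fg_ref, grid_stride_px=24, normalization_population="samples"
        )
        assert np.nanmax(res.raw) < 1e-6
        assert np.nanmean(res.z) < -1.0
        assert (res.z[np.isfinite(res.z)] < 0).all()


class TestShuffledBaseline:
    def test_static_gaze_makes_shuffling_a_noop(self, geometry):
        # same position every frame: permutation cannot change anything
        rng = np.random.default_rng(0)
        x = np.tile(rng.uniform(0, 720, (4, 1)), (1, 6))
        y = np.tile(rng.uniform(0, 480, (4, 1)), (1, 6))
        fg = FrameGaze(geometry, list("abcd"), x, y, np.ones((4, 6), bool))
        base = shuffled_baseline(fg, seed=3, grid_stride_px=60)
        self_cross = cross_condition_similarity(fg, fg, grid_stride_px=60)
        np.testing.assert_allclose(base.raw, self_cross.raw, atol=1e-12)
        np.testing.assert_allclose(base.z, self_cross.z, atol=1e-12)

    def test_same_seed_reproduces_result(self):
        fg = make_frame_gaze(sigma_deg=2.0, seed=6, n_viewers=5)
        r1 = shuffled_baseline(fg, seed=42, grid_stride_px=32)
        r2 = shuffled_baseline(fg, seed=42, grid_stride_px=32)
        np.testing.assert_array_equal(r1.z, r2.z)

    def test_shuffle_preserves_spatial_repertoire(self, geometry):
        fg = random_frame_gaze(geometry, 3, 20, seed=1, p_valid=0.7)
        shuffled = shuffle_frame_gaze(fg, np.random.default_rng(0))
        assert np.array_equal(shuffled.valid, fg.valid)
        for p in range(3):
            idx = fg.valid[p]
            assert sorted(shuffled.x[p, idx]) == sorted(fg.x[p, idx])

    def test_below_leave_one_out_on_synchronized_cohorts(self):
        """Chance baseline falls below true leave-one-out similarity (majority of seeds)."""
        wins = 0
        for seed in range(5):
            fg = make_frame_gaze(sigma_deg=1.0, seed=seed, n_viewers=6)
            loo = loo_gaze_similarity(fg, grid_stride_px=32)
            sh = shuffled_baseline(fg, seed=seed + 100, grid_stride_px=32)
            wins += np.nanmean(sh.z) < np.nanmean(loo.z)
        assert wins >= 4


class TestShotMeans:
    def _result(self, z):
        z = np.asarray(z, dtype=float)
        return SimilarityResult(
            participants=[f"p{i}" for i in range(z.shape[0])],
            frames=np.arange(z.shape[1]),
            raw=z.copy(),
            z=z,
            constants=NormalizationConstants(0.0, 1.0),
            mode="leave_one_out",
        )

    def test_constant_z_gives_constant_means(self):
        shots = ShotIndex([(1, 0, 2), (2, 2, 4)])
        out = shot_mean_similarity(self._result(np.full((2, 4), 0.5)), shots)
        assert (out["mean_z"] == 0.5).all()

    def test_mean_over_defined_frames_only(self):
        shots = ShotIndex([(1, 0, 4)])
        z = np.array([[1.0, np.nan, 3.0, np.nan]])
        out = shot_mean_similarity(self._result(z), shots)
        assert out["mean_z"].iloc[0] == 2.0

    def test_hand_built_two_shot_table(self):
        shots = ShotIndex([(1, 0, 2), (2, 2, 4)])
        z = np.array([[1.0, 2.0, 3.0, 4.0], [0.0, 1.0, np.nan, np.nan]])
        out = shot_mean_similarity(self._result(z), shots).set_index(
            ["participant", "shot"]
        )["mean_z"]
        assert out.loc[("p0", 1)] == 1.5
        assert out.loc[("p0", 2)] == 3.5
        assert out.loc[("p1", 1)] == 0.5
        assert np.isnan(out.loc[("p1", 2)])  # no defined frames in shot 2

    def test_shot_outside_video_rejected(self):
        shots = ShotIndex([(1, 0, 2), (2, 10, 12)])
        with pytest.raises(ValueError):
            shot_mean_similarity(self._result(np.zeros((2, 4))), shots)


class TestSynchronyRecovery:
    def test_mean_z_decreases_with_dispersion(self):
        """Tighter synthetic cohorts score higher mean similarity (majority of seeds)."""
        wins = 0
        for seed in range(5):
            means = []
            for sigma in (1.0, 3.0, 5.0):
                fg = make_frame_gaze(sigma_deg=sigma, seed=seed, n_viewers=6)
                res = loo_gaze_similarity(fg, grid_stride_px=32)
                means.append(np.nanmean(res.z))
            wins += means[0] > means[1] > means[2]
        assert wins >= 3
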