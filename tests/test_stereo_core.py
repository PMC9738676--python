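import numpy as np
import pytest

from stereotrap.stereo_core import (
    DepthMap,
    DisparityMap,
    RectifiedPair,
    StereoRig,
    apply_rectification,
    build_cost_volume,
    depth_to_disparity,
    disparity_from_cost_volume,
    disparity_to_depth,
)

from conftest import make_shifted_pair


def brute_force_cost_volume(left, right, D, c):
    """Independent triple-loop oracle for the SSD column-patch cost."""
    H, W = left.shape
    V = np.full((H, W, D), np.nan)
    for j in range(H):
        for i in range(W):
            for d in range(D):
                if i - d < 0 or j - c < 0 or j + c >= H:
                    continue
                V[j, i, d] = sum(
                    (left[j + dj, i] - right[j + dj, i - d]) ** 2
                    for dj in range(-c, c + 1)
                )
    return V


class TestStereoRig:
    def test_valid(self):
        rig = StereoRig(0.5, 1000.0, 64, 48)
        assert rig.bf == 500.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(baseline_m=0.0, focal_px=1000.0, image_width=64, image_height=48),
            dict(baseline_m=0.5, focal_px=-1.0, image_width=64, image_height=48),
            dict(baseline_m=0.5, focal_px=1000.0, image_width=0, image_height=48),
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            StereoRig(**kwargs)


class TestRectifiedPair:
    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="differ"):
            RectifiedPair(left=np.zeros((4, 4)), right=np.zeros((4, 5)))

    def test_non_finite(self):
        bad = np.zeros((4, 4))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            RectifiedPair(left=bad, right=np.zeros((4, 4)))

    def test_empty(self):
        with pytest.raises(ValueError):
            RectifiedPair(left=np.zeros((0, 4)), right=np.zeros((0, 4)))


class TestBuildCostVolume:
    def test_identical_images_zero_cost_at_d0(self, rng):
        img = rng.uniform(0, 255, size=(10, 12))
        pair = RectifiedPair(left=img, right=img.copy())
        vol = build_cost_volume(pair, max_disparity=4, patch_half_height=1)
        interior = vol.values[1:-1, :, 0]
        assert np.allclose(interior, 0.0)

    def test_shifted_pair_argmin_at_shift(self, rng):
        pair = make_shifted_pair(rng, shape=(20, 32), shift=4)
        vol = build_cost_volume(pair, max_disparity=8, patch_half_height=1)
        disp = disparity_from_cost_volume(vol)
        interior = disp.values[1:-1, 4:-4]
        assert np.all(interior[np.isfinite(interior)] == 4)

    def test_hand_computed_one_row(self):
        # 1-row pair, c=0: V(1,0,0)=(7-5)^2=4, V(1,0,1)=(7-9)^2=4
        a = np.array([[5.0, 7.0, 9.0]])
        b = np.array([[9.0, 5.0, 7.0]])
        pair = RectifiedPair(left=a, right=b)
        vol = build_cost_volume(pair, max_disparity=2, patch_half_height=0)
        assert vol.values[0, 1, 0] == pytest.approx(4.0)
        assert vol.values[0, 1, 1] == pytest.approx(4.0)
        # brute-force oracle agreement on the same tiny input
        oracle = brute_force_cost_volume(a, b, 2, 0)
        np.testing.assert_array_equal(np.isnan(vol.values), np.isnan(oracle))
        np.testing.assert_allclose(
            np.nan_to_num(vol.values), np.nan_to_num(oracle)
        )

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("c", [0, 1, 2])
    def test_oracle_equivalence_random(self, seed, c):
        rng = np.random.default_rng(seed)
        H, W = rng.integers(2 * c + 1, 17, size=2)
        D = int(rng.integers(1, min(9, W + 1)))
        left = rng.uniform(0, 255, size=(H, W))
        right = rng.uniform(0, 255, size=(H, W))
        vol = build_cost_volume(
            RectifiedPair(left=left, right=right), D, c
        )
        oracle = brute_force_cost_volume(left, right, D, c)
        np.testing.assert_array_equal(np.isnan(vol.values), np.isnan(oracle))
        np.testing.assert_allclose(
            np.nan_to_num(vol.values), np.nan_to_num(oracle), atol=1e-9
        )

    def test_cost_non_negative_and_zero_iff_identical(self, rng):
        left = rng.uniform(0, 255, size=(12, 14))
        right = rng.uniform(0, 255, size=(12, 14))
        vol = build_cost_volume(RectifiedPair(left=left, right=right), 5, 1)
        finite = vol.values[np.isfinite(vol.values)]
        assert np.all(finite >= 0)
        assert not np.any(finite == 0)  # iid continuous texture never matches

    def test_errors(self, rng):
        pair = make_shifted_pair(rng, shape=(8, 8), shift=1)
        with pytest.raises(ValueError, match="exceeds image width"):
            build_cost_volume(pair, max_disparity=9, patch_half_height=0)
        with pytest.raises(ValueError):
            build_cost_volume(pair, max_disparity=0, patch_half_height=0)
        with pytest.raises(ValueError):
            build_cost_volume(pair, max_disparity=2, patch_half_height=-1)

    def test_square_window_matches_column_oracle_summed(self, rng):
        left = rng.uniform(0, 255, size=(10, 12))
        right = rng.uniform(0, 255, size=(10, 12))
        c = 1
        vol = build_cost_volume(
            RectifiedPair(left=left, right=right), 4, c, square_window=True
        )
        col = brute_force_cost_volume(left, right, 4, c)
        H, W, D = col.shape
        for j in range(c, H - c):
            for i in range(c, W - c):
                for d in range(D):
                    window = col[j, i - c : i + c + 1, d]
                    expected = np.nan if np.isnan(window).any() else window.sum()
                    got = vol.values[j, i, d]
                    if np.isnan(expected):
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(expected)


class TestWinnerTakeAll:
    def test_tie_breaks_to_smaller_d(self):
        V = np.full((1, 1, 4), np.nan)
        V[0, 0, :] = [3.0, 1.0, 1.0, 5.0]
        from stereotrap.stereo_core import CostVolume

        disp = disparity_from_cost_volume(
            CostVolume(values=V, max_disparity=4, patch_half_height=0)
        )
        assert disp.values[0, 0] == 1.0

    def test_all_invalid_pixel_is_invalid(self):
        from stereotrap.stereo_core import CostVolume

        V = np.full((2, 2, 3), np.nan)
        V[0, 0, :] = [2.0, 1.0, 3.0]
        disp = disparity_from_cost_volume(
            CostVolume(values=V, max_disparity=3, patch_half_height=0)
        )
        assert disp.values[0, 0] == 1.0
        assert np.isnan(disp.values[1, 1])

    def test_subpixel_refines_toward_true_minimum(self):
        from stereotrap.stereo_core import CostVolume

        # parabola with true minimum at d = 2.25
        d = np.arange(5, dtype=float)
        V = ((d - 2.25) ** 2)[None, None, :]
        disp = disparity_from_cost_volume(
            CostVolume(values=V, max_disparity=5, patch_half_height=0), subpixel=True
        )
        assert disp.values[0, 0] == pytest.approx(2.25, abs=1e-9)

    def test_subpixel_disabled_returns_integer(self, rng):
        pair = make_shifted_pair(rng, shape=(12, 20), shift=3)
        vol = build_cost_volume(pair, 6, 1)
        disp = disparity_from_cost_volume(vol, subpixel=False)
        vals = disp.values[np.isfinite(disp.values)]
        assert np.all(vals == np.round(vals))


class TestDepthConversion:
    def test_direct_substitution(self, rig):
        disp = DisparityMap(values=np.full((2, 2), 100.0))
        depth = disparity_to_depth(disp, rig)
        assert np.allclose(depth.values, 5.0)

    def test_zero_disparity_invalid(self, rig):
        disp = DisparityMap(values=np.array([[0.0, 50.0]]))
        depth = disparity_to_depth(disp, rig)
        assert np.isnan(depth.values[0, 0])
        assert depth.values[0, 1] == pytest.approx(10.0)

    def test_roundtrip(self, rig, rng):
        vals = rng.uniform(1.0, 128.0, size=(16, 16))
        vals[0, 0] = np.nan
        vals[1, 1] = 0.0
        disp = DisparityMap(values=vals)
        back = depth_to_disparity(disparity_to_depth(disp, rig), rig)
        ok = np.isfinite(vals) & (vals > 0)
        assert np.allclose(back.values[ok], vals[ok], rtol=1e-9)
        assert np.isnan(back.values[0, 0])
        assert np.isnan(back.values[1, 1])

    def test_inverse_example(self, rig):
        depth = DepthMap(values=np.array([[5.0, np.nan, -1.0]]))
        disp = depth_to_disparity(depth, rig)
        assert disp.values[0, 0] == pytest.approx(100.0)
        assert np.isnan(disp.values[0, 1])
        assert np.isnan(disp.values[0, 2])

    def test_far_limit(self, rig):
        depth = DepthMap(values=np.array([[1e12]]))
        disp = depth_to_disparity(depth, rig)
        assert disp.values[0, 0] == pytest.approx(0.0, abs=1e-6)


class TestRectification:
    def test_identity_maps(self, rng):
        img = rng.uniform(0, 255, size=(8, 10))
        yy, xx = np.mgrid[0:8, 0:10].astype(float)
        pair = apply_rectification(img, img, (xx, yy, xx, yy))
        np.testing.assert_allclose(pair.left, img)
        np.testing.assert_allclose(pair.right, img)

    def test_horizontal_shift_maps(self, rng):
        img = rng.uniform(0, 255, size=(8, 10))
        yy, xx = np.mgrid[0:8, 0:10].astype(float)
        pair = apply_rectification(img, img, (xx + 2, yy, xx, yy))
        np.testing.assert_allclose(pair.left[:, :8], img[:, 2:])

    def test_out_of_bounds_zeroed(self, rng):
        img = rng.uniform(1, 255, size=(8, 10))
        yy, xx = np.mgrid[0:8, 0:10].astype(float)
        pair = apply_rectification(img, img, (xx + 100, yy, xx, yy))
        assert np.all(pair.left == 0.0)

    def test_mismatched_maps_error(self, rng):
        img = rng.uniform(0, 255, size=(8, 10))
        yy, xx = np.mgrid[0:8, 0:10].astype(float)
        with pytest.raises(ValueError, match="share one shape"):
            apply_rectification(img, img, (xx, yy, xx[:4], yy))


class TestNoiseDegradation:
    def test_monotone_degradation_in_expectation(self):
        # recovered-pixel fraction should not increase with noise variance
        sigmas = [0.0, 20.0, 60.0, 150.0]
        mean_fracs = []
        for sigma in sigmas:
            fracs = []
            for seed in range(8):
                rng = np.random.default_rng(seed)
                pair = make_shifted_pair(rng, shape=(24, 32), shift=3)
                noisy = RectifiedPair(
                    left=pair.left,
                    right=pair.right + rng.normal(0, sigma, pair.right.shape),
                )
                vol = build_cost_volume(noisy, 6, 1)
                disp = disparity_from_cost_volume(vol)
                interior = disp.values[1:-1, 3:-3]
                interior = interior[np.isfinite(interior)]
                fracs.append(np.mean(interior == 3))
            mean_fracs.append(np.mean(fracs))
        assert all(
            a >= b - 1e-9 for a, b in zip(mean_fracs, mean_fracs[1:])
        ), mean_fracs
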