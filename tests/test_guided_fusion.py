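import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import focusfuse as ff
from focusfuse.errors import ConfigError, DimensionMismatchError, InputError
from focusfuse.guided_fusion import max_window
from oracles import box_mean_bruteforce, guided_filter_bruteforce


class TestGuidedFilter:
    def test_self_guidance_eps_zero_is_identity(self, rng):
        img = rng.random((12, 17))
        out = ff.guided_filter(img, img, 2, 0.0)
        np.testing.assert_allclose(out, img, atol=1e-12)

    def test_constant_guidance_reduces_to_double_box_mean(self, rng):
        """With a constant guidance a = 0 everywhere, so the output is the
        box mean of the per-window means of the input."""
        img = rng.random((10, 10))
        out = ff.guided_filter(np.full((10, 10), 0.7), img, 1, 1e-3)
        expected = box_mean_bruteforce(box_mean_bruteforce(img, 1), 1)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    @pytest.mark.parametrize("eps", [0.0, 1e-2])
    def test_matches_per_window_least_squares(self, rng, eps):
        g = rng.random((7, 7))
        p = rng.random((7, 7))
        out = ff.guided_filter(g, p, 1, eps if eps else 0.01)
        oracle = guided_filter_bruteforce(g, p, 1, eps if eps else 0.01)
        assert np.abs(out - oracle).max() < 1e-10

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        h=st.integers(4, 12),
        w=st.integers(4, 12),
        r=st.integers(1, 3),
        eps=st.sampled_from([0.0, 1e-3, 1e-1]),
    )
    def test_oracle_equivalence_property(self, seed, h, w, r, eps):
        rng = np.random.default_rng(seed)
        g = rng.random((h, w))
        p = rng.random((h, w))
        out = ff.guided_filter(g, p, r, eps)
        assert np.abs(out - guided_filter_bruteforce(g, p, r, eps)).max() < 1e-10

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DimensionMismatchError):
            ff.guided_filter(np.zeros((4, 4)), np.zeros((4, 5)), 1, 0.1)

    def test_eps_monotonically_smooths(self):
        """Increasing eps never increases the total variation of the weight
        map on a half-plane-mask instance."""
        img = ff.make_scene("texture", 64, 64, seed=9).reference
        mask = np.zeros((64, 64))
        mask[:, :32] = 1.0
        tvs = []
        for eps in [1e-4, 1e-3, 1e-2, 1e-1, 1.0]:
            w = ff.guided_filter(mask, img * mask, 4, eps)
            tv = np.abs(np.diff(w, axis=0)).sum() + np.abs(np.diff(w, axis=1)).sum()
            tvs.append(tv)
        assert all(a >= b - 1e-9 for a, b in zip(tvs, tvs[1:]))


class TestWindowSchedule:
    def test_arithmetic_progression(self):
        assert ff.window_schedule(1, 2) == 1
        assert ff.window_schedule(4, 2) == 7
        radii = [ff.window_schedule(n, 3) for n in range(1, 6)]
        assert radii == sorted(set(radii))  # strictly increasing

    def test_invalid_arguments(self):
        with pytest.raises(ConfigError):
            ff.window_schedule(0, 2)
        with pytest.raises(ConfigError):
            ff.window_schedule(1, 0)

    def test_quarter_size_cap(self):
        assert max_window((2048, 2048)) == 512
        assert max_window((2048, 1024)) == 256

    def test_full_masks_select_smallest_window(self):
        stack = ff.ImageStack(np.full((2, 64, 64), 0.5))
        masks = [ff.FocusMask(np.ones((64, 64)), i, "dilated") for i in range(2)]
        assert ff.select_window(stack, masks, ff.GuidedFilterParams()) == 1

    def test_gap_between_masks_forces_larger_window(self):
        """Weight must bleed across a zero-weight gap before coverage = 1."""
        h = w = 64
        frames = np.full((2, h, w), 0.5)
        left = np.zeros((h, w), dtype=bool)
        left[:, :27] = True
        right = np.zeros((h, w), dtype=bool)
        right[:, 37:] = True  # 9-pixel-wide uncovered gap between masks
        masks = [ff.FocusMask(left, 0, "dilated"), ff.FocusMask(right, 1, "dilated")]
        params = ff.GuidedFilterParams(coverage_frac=1.0)
        r = ff.select_window(ff.ImageStack(frames), masks, params)
        assert r > 1
        # replaying the schedule confirms r is the first covering radius
        for n in range(1, 20):
            cand = ff.window_schedule(n, params.scale_factor)
            if cand >= r:
                break
            weights = ff.compute_weights(
                ff.ImageStack(frames), masks, params, r=cand
            ).weights
            assert (weights.max(axis=0) > params.coverage_tau).mean() < 1.0


class TestComputeWeights:
    def test_single_frame_full_mask_normalizes_to_one(self):
        stack = ff.ImageStack(np.full((1, 32, 32), 0.6))
        masks = [ff.FocusMask(np.ones((32, 32)), 0, "dilated")]
        ws = ff.compute_weights(stack, masks, ff.GuidedFilterParams(eps=0.0, window=2))
        np.testing.assert_allclose(ws.normalize().weights[0], 1.0)

    def test_zero_mask_gives_zero_weight(self, rng):
        frames = rng.random((2, 32, 32))
        masks = [
            ff.FocusMask(np.ones((32, 32)), 0, "dilated"),
            ff.FocusMask(np.zeros((32, 32)), 1, "dilated"),
        ]
        ws = ff.compute_weights(ff.ImageStack(frames), masks, ff.GuidedFilterParams(window=2))
        np.testing.assert_allclose(ws.weights[1], 0.0, atol=1e-15)

    def test_weights_decay_across_mask_boundary(self):
        """Edge-aware softening: along a transect perpendicular to a
        half-plane mask edge the weight decays from inside to outside."""
        h = w = 64
        frames = np.full((1, h, w), 0.8)
        mask = np.zeros((h, w), dtype=bool)
        mask[:, :32] = True
        ws = ff.compute_weights(
            ff.ImageStack(frames),
            [ff.FocusMask(mask, 0, "dilated")],
            ff.GuidedFilterParams(window=6),
        )
        transect = ws.weights[0][32, 24:40]
        assert np.all(np.diff(transect) < 0)  # strict decay inside -> outside
        assert transect[0] > 0.5 and transect[-1] < 0.1

    def test_mask_count_mismatch_rejected(self, rng):
        stack = ff.ImageStack(rng.random((3, 16, 16)))
        with pytest.raises(InputError):
            ff.compute_weights(stack, [ff.FocusMask(np.ones((16, 16)))], ff.GuidedFilterParams())


class TestFuse:
    def test_single_frame_passthrough(self, rng):
        img = rng.random((16, 16))
        stack = ff.ImageStack(img[None])
        res = ff.fuse(stack, ff.WeightStack(np.ones((1, 16, 16))))
        np.testing.assert_allclose(res.fused, img)
        assert np.all(res.index_map == 0)

    def test_hand_computed_weighted_average(self):
        """Raw weights 1 and 3 on values 10/255 and 20/255 -> 17.5/255."""
        frames = np.stack([np.full((4, 4), 10 / 255), np.full((4, 4), 20 / 255)])
        weights = ff.WeightStack(
            np.stack([np.ones((4, 4)), 3 * np.ones((4, 4))])
        )
        res = ff.fuse(ff.ImageStack(frames), weights)
        np.testing.assert_allclose(res.fused, 17.5 / 255)
        assert np.all(res.index_map == 1)

    def test_equal_weights_give_arithmetic_mean(self, rng):
        frames = rng.random((3, 8, 8))
        res = ff.fuse(ff.ImageStack(frames), ff.WeightStack(np.ones((3, 8, 8))))
        np.testing.assert_allclose(res.fused, frames.mean(axis=0))
        assert np.all(res.index_map == 0)  # ties -> lowest frame index

    def test_all_zero_weights_fall_back_to_mean(self, rng):
        frames = rng.random((2, 8, 8))
        res = ff.fuse(ff.ImageStack(frames), ff.WeightStack(np.zeros((2, 8, 8))))
        assert res.fallback_mask.all()
        np.testing.assert_allclose(res.fused, frames.mean(axis=0))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 5))
    def test_fusion_is_convex_combination(self, seed, n):
        rng = np.random.default_rng(seed)
        frames = rng.random((n, 10, 10))
        weights = ff.WeightStack(rng.random((n, 10, 10)))
        res = ff.fuse(ff.ImageStack(frames), weights)
        lo = frames.min(axis=0) - 1e-12
        hi = frames.max(axis=0) + 1e-12
        ok = ~res.fallback_mask
        assert np.all(res.fused[ok] >= lo[ok]) and np.all(res.fused[ok] <= hi[ok])

    def test_permutation_equivariance(self, rng):
        frames = rng.random((3, 12, 12))
        weights = rng.random((3, 12, 12)) + 0.01  # no exact ties
        perm = [2, 0, 1]
        res = ff.fuse(ff.ImageStack(frames), ff.WeightStack(weights))
        res_p = ff.fuse(ff.ImageStack(frames[perm]), ff.WeightStack(weights[perm]))
        np.testing.assert_allclose(res.fused, res_p.fused, atol=1e-12)
        inverse = np.argsort(perm)
        np.testing.assert_array_equal(res.index_map, np.asarray(perm)[res_p.index_map])


class TestFuseStack:
    def test_identical_sharp_frames_reproduce_the_frame(self):
        img = ff.make_scene("texture", 128, 128, seed=5).reference
        stack = ff.ImageStack(np.stack([img] * 4))
        res = ff.fuse_stack(stack)
        ok = ~res.fallback_mask
        assert np.abs(res.fused - img)[ok].max() < 1e-6

    def test_single_frame_rejected(self, rng):
        with pytest.raises(InputError):
            ff.fuse_stack(ff.ImageStack(rng.random((1, 64, 64))))

    def test_constant_stack_warns_and_returns_mean(self):
        stack = ff.ImageStack(np.full((2, 64, 64), 0.5))
        with pytest.warns(UserWarning, match="no focus"):
            res = ff.fuse_stack(stack)
        np.testing.assert_allclose(res.fused, 0.5)
        assert res.fallback_mask.all()

    def test_twenty_frame_stack_covers_depth_bands(self):
        scene = ff.make_scene("cells", 256, 256, seed=3, depth="bands", n_bands=5)
        synth = ff.render_stack(scene, 20, seed=3)
        res = ff.fuse_stack(synth.stack)
        assert len(np.unique(res.index_map)) >= 3

    def test_fused_beats_best_single_frame_on_disjoint_sharp_regions(self):
        """Parameter-free fidelity: piecewise-constant depth, disjoint sharp
        regions -> fused PSNR above every single frame's PSNR."""
        ref = ff.make_scene("cells", 256, 256, seed=11).reference
        synth = ff.fig4_protocol(ref, n_frames=3, sigma=3.0, seed=11)
        res = ff.fuse_stack(synth.stack)
        fused_psnr = ff.psnr(ref, res.fused)
        frame_psnrs = [ff.psnr(ref, fr) for fr in synth.stack.frames]
        assert fused_psnr > max(frame_psnrs)
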