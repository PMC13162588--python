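"""Oversampling statistics, augmentation behavior, and preprocessing
determinism."""

import numpy as np
import pytest

from cattleact import NORMAL, PROTECTIVE
from cattleact.data_ava import AvaRecord, ClipPair
from cattleact.sampler import (
    AugmentConfig, OversampleConfig,
    augment_protective, build_minority_pool, oversample_batch, preprocess,
)


def rec(video, t, action):
    return AvaRecord(video, t, (0.1, 0.1, 0.6, 0.6), action, 0)


def make_clip(seed=0, t_slow=2, alpha=4, hw=(24, 24), dtype=np.uint8):
    rng = np.random.default_rng(seed)
    shape_fast = (t_slow * alpha, *hw, 3)
    fast = rng.integers(0, 256, size=shape_fast).astype(dtype)
    slow = fast[::alpha].copy()
    return ClipPair(slow, fast, 1, "v")


class TestMinorityPool:
    def test_all_normal_gives_empty_pool(self):
        records = [rec("a", t, NORMAL) for t in range(5)]
        assert build_minority_pool(records) == []

    def test_single_protective_keyframe(self):
        records = [rec("a", 0, NORMAL), rec("a", 1, PROTECTIVE),
                   rec("b", 0, NORMAL)]
        assert build_minority_pool(records) == [("a", 1)]

    def test_pool_matches_brute_force_on_random_records(self):
        rng = np.random.default_rng(7)
        records = [rec(f"v{rng.integers(5)}", int(rng.integers(10)),
                       PROTECTIVE if rng.random() < 0.3 else NORMAL)
                   for _ in range(200)]
        pool = build_minority_pool(records)
        brute = {(r.video_id, r.timestamp) for r in records
                 if r.action_id == PROTECTIVE}
        assert set(pool) == brute
        assert pool == sorted(pool)  # deterministic ordering


class TestOversampling:
    POOL = [("a", 0), ("a", 3), ("b", 1)]

    def test_p_zero_is_identity(self):
        keys = [("x", 0), ("y", 1)]
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert oversample_batch(keys, self.POOL,
                                    OversampleConfig(p=0.0), rng) == keys

    def test_p_one_singleton_pool_replaces_everything(self):
        keys = [("x", 0), ("y", 1), ("z", 2)]
        rng = np.random.default_rng(0)
        out = oversample_batch(keys, [("k", 9)], OversampleConfig(p=1.0), rng)
        assert out == [("k", 9)] * 3

    def test_empty_pool_trigger_is_noop_and_counted(self):
        keys = [("x", 0)]
        counters = {}
        out = oversample_batch(keys, [], OversampleConfig(p=1.0),
                               np.random.default_rng(0), counters)
        assert out == keys and counters["empty_pool"] == 1

    def test_trigger_frequency_within_3_sigma(self):
        """Empirical trigger rate over 10,000 batches at p=0.5 stays within
        the binomial 3-sigma band (0.5 +/- 0.015)."""
        cfg = OversampleConfig(p=0.5)
        rng = np.random.default_rng(123)
        keys = [("x", 0), ("y", 1)]
        triggers = 0
        for _ in range(10_000):
            out = oversample_batch(keys, self.POOL, cfg, rng)
            triggers += out != keys
        assert abs(triggers / 10_000 - 0.5) < 0.015

    def test_output_keys_stay_inside_pool_union_batch(self):
        rng = np.random.default_rng(5)
        keys = [("x", 0), ("y", 1)]
        allowed = set(self.POOL) | set(keys)
        for p in (0.0, 0.3, 1.0):
            for _ in range(100):
                out = oversample_batch(keys, self.POOL,
                                       OversampleConfig(p=p), rng)
                assert len(out) == len(keys)
                assert set(out) <= allowed

    def test_deterministic_given_rng_state(self):
        cfg = OversampleConfig(p=0.7)
        keys = [("x", 0), ("y", 1), ("z", 2)]
        a = [oversample_batch(keys, self.POOL, cfg, np.random.default_rng(9))
             for _ in range(3)]
        b = [oversample_batch(keys, self.POOL, cfg, np.random.default_rng(9))
             for _ in range(3)]
        assert a == b


class TestAugmentation:
    def test_all_probabilities_zero_is_bit_exact_identity(self):
        clip = make_clip()
        cfg = AugmentConfig(p_color_jitter=0, p_color_enhance=0, p_occlusion=0)
        out = augment_protective(clip, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(out.slow_frames, clip.slow_frames)
        np.testing.assert_array_equal(out.fast_frames, clip.fast_frames)

    def test_certain_occlusion_masks_expected_area_on_all_frames(self):
        clip = make_clip(seed=3, hw=(40, 40))
        cfg = AugmentConfig(p_color_jitter=0, p_color_enhance=0,
                            p_occlusion=1.0, occlusion_area_frac=0.10)
        out = augment_protective(clip, cfg, np.random.default_rng(1))
        masked = np.all(out.fast_frames == 128, axis=-1)  # mid-gray fill
        frac = masked[0].mean()
        assert 0.05 < frac < 0.20
        # identical mask position on every frame of both stacks
        for frame_mask in masked[1:]:
            np.testing.assert_array_equal(frame_mask, masked[0])
        slow_masked = np.all(out.slow_frames == 128, axis=-1)
        np.testing.assert_array_equal(slow_masked[0], masked[0])

    def test_activation_frequencies_match_configured_probabilities(self):
        """Per-transform activation over 2,000 draws lands within 3 sigma of
        the 0.5 / 0.7 / 0.3 defaults."""
        cfg = AugmentConfig()
        rng = np.random.default_rng(77)
        clip = make_clip(hw=(12, 12), t_slow=1)
        n = 2000
        counters = {}
        for _ in range(n):
            augment_protective(clip, cfg, rng, counters)
        for name, p in (("color_jitter", 0.5), ("color_enhance", 0.7),
                        ("occlusion", 0.3)):
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(counters[name] / n - p) < 3 * sigma

    def test_transforms_preserve_range_and_shapes(self):
        clip = make_clip(seed=9)
        out = augment_protective(clip, AugmentConfig(), np.random.default_rng(4))
        assert out.fast_frames.shape == clip.fast_frames.shape
        assert out.fast_frames.dtype == np.uint8
        assert out.slow_frames.min() >= 0 and out.slow_frames.max() <= 255


class TestPreprocess:
    def test_eval_mode_is_deterministic(self):
        clip = make_clip(seed=2)
        a = preprocess(clip, (16, 16), train_mode=False)
        b = preprocess(clip, (16, 16), train_mode=False)
        np.testing.assert_array_equal(a.fast_frames, b.fast_frames)
        np.testing.assert_array_equal(a.slow_frames, b.slow_frames)

    @pytest.mark.parametrize("hw", [(24, 24), (17, 31)])
    def test_output_spatial_dims_match_target(self, hw):
        clip = make_clip(seed=5, hw=hw)
        out = preprocess(clip, (16, 20), train_mode=False)
        assert out.slow_frames.shape[1:3] == (16, 20)
        assert out.fast_frames.shape[1:3] == (16, 20)

    def test_pca_jitter_scale_zero_matches_color_jitter_only(self):
        clip = make_clip(seed=6)
        a = preprocess(clip, (16, 16), True, np.random.default_rng(3),
                       pca_jitter_scale=0.0)
        # same rng stream: jitter params identical, then zero-scale offset
        b = preprocess(clip, (16, 16), True, np.random.default_rng(3),
                       pca_jitter_scale=1e-12)
        np.testing.assert_allclose(a.fast_frames, b.fast_frames, atol=1e-7)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            preprocess(make_clip(), (0, 16), train_mode=False)
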