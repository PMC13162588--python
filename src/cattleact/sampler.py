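"""Timing-aware minority oversampling and protective-class augmentation.

Oversampling operates on batch *indices*, not pixels: a pool of (video,
timestamp) keyframe keys that carry at least one protective box is built
once, and before each training batch a uniform [0, 1) draw against the
trigger probability ``p`` decides whether the batch's keys are replaced by
uniform draws from that pool.  Because replacements are themselves valid
keyframes, the subsequent clip cut stays aligned with real video timing.

Augmentation targets protective clips with three independently triggered
transforms — color jitter (50%), color enhancement (70%), random occlusion
(30%) by default — each applied with identical parameters to every frame of
the clip so motion cues survive.  A unified preprocessing step (resize,
normalization, optional shared-parameter color/PCA jitter in training mode)
finishes the loader path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import PROTECTIVE
from .data_ava import AvaRecord, ClipPair

__all__ = [
    "OversampleConfig", "AugmentConfig",
    "build_minority_pool", "oversample_batch",
    "augment_protective", "preprocess",
]

# channel statistics used to center inputs (standard video-model constants)
_MEAN = np.array([0.45, 0.45, 0.45])
_STD = np.array([0.225, 0.225, 0.225])


@dataclass(frozen=True)
class OversampleConfig:
    p: float = 0.5
    seed: int = 0
    per_sample: bool = False

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("trigger probability must lie in [0, 1]")


@dataclass(frozen=True)
class AugmentConfig:
    p_color_jitter: float = 0.5
    p_color_enhance: float = 0.7
    p_occlusion: float = 0.3
    occlusion_area_frac: float = 0.10
    pca_jitter_scale: float = 0.1

    def __post_init__(self):
        for name in ("p_color_jitter", "p_color_enhance", "p_occlusion"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def build_minority_pool(records: Sequence[AvaRecord]) -> list[tuple[str, int]]:
    """Deduplicated, sorted keyframe keys holding >= 1 protective box."""
    return sorted({(r.video_id, r.timestamp) for r in records
                   if r.action_id == PROTECTIVE})


def oversample_batch(batch_keys: Sequence, pool: Sequence,
                     cfg: OversampleConfig, rng: np.random.Generator,
                     counters: dict | None = None) -> list:
    """Possibly replace the batch's keyframe keys with minority-pool draws.

    Output length always equals input length; with an empty pool a trigger
    is a no-op (counted in ``counters['empty_pool']`` when provided).
    """
    if len(batch_keys) < 1:
        raise ValueError("batch must contain at least one key")
    keys = list(batch_keys)
    r = rng.random()
    if r >= cfg.p:
        return keys
    if len(pool) == 0:
        if counters is not None:
            counters["empty_pool"] = counters.get("empty_pool", 0) + 1
        return keys
    if counters is not None:
        counters["triggered"] = counters.get("triggered", 0) + 1
    pool = list(pool)
    if cfg.per_sample:
        out = []
        for k in keys:
            out.append(pool[rng.integers(len(pool))]
                       if rng.random() < cfg.p else k)
        return out
    return [pool[rng.integers(len(pool))] for _ in keys]


# ---------------------------------------------------------------- transforms
def _gray(x: np.ndarray) -> np.ndarray:
    return x.mean(axis=-1, keepdims=True)


def _apply_jitter(x, brightness, contrast, saturation):
    x = x * brightness
    mean = x.mean()
    x = (x - mean) * contrast + mean
    g = _gray(x)
    return g + (x - g) * saturation


def _apply_enhance(x, sat_gain, con_gain):
    g = _gray(x)
    x = g + (x - g) * sat_gain
    mean = x.mean()
    return (x - mean) * con_gain + mean


def _occlusion_params(shape, frac: float, rng: np.random.Generator):
    h, w = shape
    area = frac * h * w
    aspect = rng.uniform(0.5, 2.0)
    oh = int(np.clip(round(np.sqrt(area * aspect)), 1, h))
    ow = int(np.clip(round(area / oh), 1, w))
    y = int(rng.integers(0, h - oh + 1))
    x = int(rng.integers(0, w - ow + 1))
    return y, x, oh, ow


def augment_protective(clip: ClipPair, cfg: AugmentConfig,
                       rng: np.random.Generator,
                       counters: dict | None = None) -> ClipPair:
    """Apply the three protective-class transforms to both frame stacks.

    Each transform triggers independently with its configured probability;
    parameters are drawn once per clip and shared across frames and between
    the slow and fast stacks (the slow stack is a subsequence of the fast
    one, so temporal/color consistency matters).  Boxes and labels are
    untouched by design: occlusion and color changes never move the animal.
    Pixel range ([0, 255] or [0, 1]) is preserved.
    """
    hi = 255.0 if (clip.fast_frames.dtype == np.uint8
                   or clip.fast_frames.max() > 1.5) else 1.0
    in_dtype = clip.fast_frames.dtype
    slow = clip.slow_frames.astype(np.float64)
    fast = clip.fast_frames.astype(np.float64)

    do_jitter = rng.random() < cfg.p_color_jitter
    do_enhance = rng.random() < cfg.p_color_enhance
    do_occlude = rng.random() < cfg.p_occlusion
    if counters is not None:
        for name, fired in (("color_jitter", do_jitter),
                            ("color_enhance", do_enhance),
                            ("occlusion", do_occlude)):
            counters[name] = counters.get(name, 0) + int(fired)

    if do_jitter:
        b, c, s = rng.uniform(0.8, 1.2, size=3)
        slow, fast = _apply_jitter(slow, b, c, s), _apply_jitter(fast, b, c, s)
    if do_enhance:
        sg, cg = rng.uniform(1.0, 1.5, size=2)
        slow, fast = _apply_enhance(slow, sg, cg), _apply_enhance(fast, sg, cg)
    if do_occlude:
        y, x, oh, ow = _occlusion_params(slow.shape[1:3],
                                         cfg.occlusion_area_frac, rng)
        slow[:, y:y + oh, x:x + ow] = 0.5 * hi
        fast[:, y:y + oh, x:x + ow] = 0.5 * hi

    slow = np.clip(slow, 0.0, hi)
    fast = np.clip(fast, 0.0, hi)
    if in_dtype == np.uint8:
        slow, fast = slow.round().astype(np.uint8), fast.round().astype(np.uint8)
    return ClipPair(slow, fast, clip.keyframe_timestamp, clip.source_video)


# --------------------------------------------------------------- preprocessing
def _ensure_rgb(frames: np.ndarray) -> np.ndarray:
    if frames.ndim == 3:  # grayscale [T, H, W]
        return np.repeat(frames[..., None], 3, axis=-1)
    return frames


def _resize_stack(frames: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    if frames.shape[1:3] == tuple(target):
        return frames.astype(np.float64)
    from skimage.transform import resize

    out = np.empty((frames.shape[0], *target, frames.shape[3]))
    for i, frame in enumerate(frames):
        out[i] = resize(frame, target, order=1, mode="edge",
                        anti_aliasing=False, preserve_range=True)
    return out


def _pca_jitter_offset(pixels: np.ndarray, scale: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Lighting perturbation along the principal axes of the clip's RGB
    covariance; magnitude ``scale`` standard deviations, one draw per clip."""
    cov = np.cov(pixels.reshape(-1, 3).T)
    eigval, eigvec = np.linalg.eigh(cov)
    alphas = rng.normal(0.0, scale, size=3)
    return eigvec @ (alphas * np.sqrt(np.maximum(eigval, 0.0)))


def preprocess(clip: ClipPair, target_size: tuple[int, int],
               train_mode: bool, rng: np.random.Generator | None = None,
               pca_jitter_scale: float = 0.1) -> ClipPair:
    """Resize and normalize a clip into model-ready float stacks.

    Output frames are [T, H, W, 3] float64 centered by fixed channel
    statistics.  In training mode a shared brightness/contrast/saturation
    jitter and a PCA lighting jitter (scale 0 disables it exactly) are
    applied with identical parameters for both stacks; evaluation mode is
    fully deterministic.
    """
    th, tw = int(target_size[0]), int(target_size[1])
    if th <= 0 or tw <= 0:
        raise ValueError("target_size must be positive")
    hi = 255.0 if (clip.fast_frames.dtype == np.uint8
                   or clip.fast_frames.max() > 1.5) else 1.0
    slow = _resize_stack(_ensure_rgb(clip.slow_frames), (th, tw)) / hi
    fast = _resize_stack(_ensure_rgb(clip.fast_frames), (th, tw)) / hi

    if train_mode:
        if rng is None:
            raise ValueError("training-mode preprocessing needs an rng")
        b, c, s = rng.uniform(0.9, 1.1, size=3)
        slow, fast = _apply_jitter(slow, b, c, s), _apply_jitter(fast, b, c, s)
        if pca_jitter_scale != 0.0:
            offset = _pca_jitter_offset(fast, pca_jitter_scale, rng)
            slow, fast = slow + offset, fast + offset
    slow = (np.clip(slow, 0.0, 1.0) - _MEAN) / _STD
    fast = (np.clip(fast, 0.0, 1.0) - _MEAN) / _STD
    return ClipPair(slow, fast, clip.keyframe_timestamp, clip.source_video)
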