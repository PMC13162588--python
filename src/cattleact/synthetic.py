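"""Deterministic synthetic videos emulating the structure of cattle
protective-behavior footage.

Each clip shows one textured "body" rectangle with an attached "appendage"
(tail-like) rectangle on a low-frequency noise background.  Normal behavior
drifts slowly and coherently; protective behavior adds a high-frequency
appendage oscillation on top of the slow body drift, so the two classes are
separable by motion rate — the cue a dual-rate (slow/fast) backbone is built
to exploit.  Keyframes are annotated at 1 Hz with the tight body+appendage
box.  Class imbalance defaults to the protective fraction of the emulated
dataset (255 of 2152 labeled keyframes, ~0.118).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import NORMAL, PROTECTIVE
from .data_ava import AvaRecord, SplitSpec, split_videos, write_ava_csv

__all__ = ["SyntheticSpec", "generate_video", "generate_dataset"]

DEFAULT_MOTION = {
    "normal": {"amplitude": 1.5, "frequency": 0.25},
    "protective": {"amplitude": 8.0, "frequency": 5.0},
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic corpus."""

    n_videos: int = 50
    frames_per_video: int = 24
    fps: int = 8
    frame_size: tuple[int, int] = (64, 64)  # (H, W)
    imbalance: float = 0.12  # protective keyframe/video fraction
    motion_profile: dict = field(default_factory=lambda: DEFAULT_MOTION)
    seed: int = 0
    noise_sigma: float = 3.0

    def __post_init__(self):
        if not 0.0 < self.imbalance < 1.0:
            raise ValueError("imbalance must lie in (0, 1)")
        if self.frames_per_video < self.fps:
            raise ValueError("need at least one keyframe per video")


def _smooth_background(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Low-frequency luminance texture the spatial attention can suppress."""
    coarse = rng.uniform(60, 120, size=(max(h // 8, 1), max(w // 8, 1), 3))
    bg = np.kron(coarse, np.ones((8, 8, 1)))[:h, :w, :]
    return bg


def generate_video(spec: SyntheticSpec, behavior: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, list[AvaRecord]]:
    """Render one clip and its 1 Hz keyframe annotations.

    Returns uint8 frames of shape [frames, H, W, 3] and one record per whole
    second, each holding the tight box around body plus appendage.
    """
    if behavior not in (NORMAL, PROTECTIVE):
        raise ValueError(f"behavior must be {NORMAL} or {PROTECTIVE}")
    h, w = spec.frame_size
    n = spec.frames_per_video
    profile = spec.motion_profile[
        "protective" if behavior == PROTECTIVE else "normal"]
    amp, freq = float(profile["amplitude"]), float(profile["frequency"])

    bg = _smooth_background(rng, h, w)
    body_h, body_w = int(h * 0.30), int(w * 0.40)
    app_h, app_w = max(int(h * 0.12), 2), max(int(w * 0.22), 3)
    texture = rng.uniform(-25, 25, size=(body_h, body_w, 1))
    body_color = rng.uniform(140, 200, size=3)
    app_color = rng.uniform(20, 60, size=3)  # dark tail against mid-gray field

    # slow coherent drift shared by both classes
    cy0 = rng.uniform(0.30, 0.55) * h
    cx0 = rng.uniform(0.25, 0.45) * w
    drift_dir = rng.uniform(-1, 1, size=2)
    drift_speed = rng.uniform(0.2, 0.5)  # px / frame
    sway_phase = rng.uniform(0, 2 * np.pi)
    osc_phase = rng.uniform(0, 2 * np.pi)

    frames = np.empty((n, h, w, 3), dtype=np.uint8)
    records: list[AvaRecord] = []
    video_id = ""  # caller assigns ids; kept in records by generate_dataset

    for f in range(n):
        t = f / spec.fps
        img = bg + rng.normal(0, spec.noise_sigma, size=(h, w, 3))
        cy = cy0 + drift_dir[0] * drift_speed * f + 1.0 * np.sin(
            2 * np.pi * 0.15 * t + sway_phase)
        cx = cx0 + drift_dir[1] * drift_speed * f
        by = int(np.clip(cy, 1, h - body_h - app_h - 2))
        bx = int(np.clip(cx, 1, w - body_w - app_w - 2))
        img[by:by + body_h, bx:bx + body_w] = body_color + texture

        # appendage hangs off the right edge of the body; its vertical offset
        # carries the class-specific motion signal
        osc = amp * np.sin(2 * np.pi * freq * t + osc_phase)
        ay = int(np.clip(by + body_h // 2 + osc, 0, h - app_h - 1))
        ax = bx + body_w
        img[ay:ay + app_h, ax:ax + app_w] = app_color

        frames[f] = np.clip(img, 0, 255).astype(np.uint8)

        if f % spec.fps == 0:
            # tight box around the extremes the appendage can reach this second
            y_lo = min(by, int(np.clip(by + body_h // 2 - abs(amp) - 1, 0, h - 1)))
            y_hi = max(by + body_h, ay + app_h)
            x_lo, x_hi = bx, ax + app_w
            box = (max(x_lo / w, 0.0), max(y_lo / h, 0.0),
                   min(x_hi / w, 1.0), min(y_hi / h, 1.0))
            records.append(AvaRecord(video_id, f // spec.fps, box, behavior, 0))
    return frames, records


def _spawn(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def generate_dataset(spec: SyntheticSpec, out_dir, overwrite: bool = False) -> dict:
    """Render the full corpus to disk: frame directories, split CSVs, manifest.

    The number of protective videos is the rounded ``n_videos * imbalance``
    (placement randomized by seed), so the realized class fraction tracks the
    requested one exactly up to rounding.  Returns the manifest dict.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty; pass overwrite")
    (out / "frames").mkdir(parents=True, exist_ok=True)

    import imageio.v3 as iio

    n_prot = int(round(spec.n_videos * spec.imbalance))
    layout_rng = _spawn(spec.seed, 0)
    prot_idx = set(layout_rng.choice(spec.n_videos, size=n_prot, replace=False))

    all_records: list[AvaRecord] = []
    video_ids, protective_videos = [], set()
    for i in range(spec.n_videos):
        behavior = PROTECTIVE if i in prot_idx else NORMAL
        vid = f"syn{i:04d}"
        video_ids.append(vid)
        if behavior == PROTECTIVE:
            protective_videos.add(vid)
        frames, records = generate_video(spec, behavior, _spawn(spec.seed, i + 1))
        vdir = out / "frames" / vid
        vdir.mkdir(exist_ok=True)
        for f, frame in enumerate(frames):
            iio.imwrite(vdir / f"{f:05d}.png", frame)
        all_records.extend(
            AvaRecord(vid, r.timestamp, r.box, r.action_id, r.entity_id)
            for r in records)

    train_ids, test_ids = split_videos(
        video_ids,
        SplitSpec(ratio=0.8, seed=spec.seed, stratify_by_protective=True),
        protective_videos=protective_videos)
    train_recs = [r for r in all_records if r.video_id in set(train_ids)]
    test_recs = [r for r in all_records if r.video_id in set(test_ids)]
    write_ava_csv(train_recs, out / "train.csv")
    write_ava_csv(test_recs, out / "test.csv")

    digest = hashlib.sha256()
    digest.update((out / "train.csv").read_bytes())
    digest.update((out / "test.csv").read_bytes())
    manifest = {
        "spec": {**asdict(spec), "frame_size": list(spec.frame_size)},
        "fps": spec.fps,
        "videos": video_ids,
        "train_videos": train_ids,
        "test_videos": test_ids,
        "protective_videos": sorted(protective_videos),
        "annotation_sha256": digest.hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
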