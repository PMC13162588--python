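"""AVA v2.2-style keyframe annotations and dual-rate clip extraction.

Annotations live in headerless CSV rows

    video_id, timestamp, x1, y1, x2, y2, action_id, entity_id

with box corners normalized to frame width/height, integer timestamps in
seconds at the 1 Hz annotation cadence, and action ids 1 (normal behavior)
and 2 (protective behavior).  This module also converts VIA 2.x rectangle
exports into that dialect, partitions datasets at the video level, and cuts
aligned (slow, fast) frame stacks around a keyframe: the raw window spans
``tau * t_slow`` frames; the slow stack takes every ``tau``-th frame and the
fast stack every ``tau / alpha``-th, so the fast stack is always ``alpha``
times longer.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import NORMAL, PROTECTIVE

__all__ = [
    "AvaRecord", "SplitSpec", "ClipPair", "AvaValidationError",
    "read_ava_csv", "write_ava_csv", "convert_via_to_ava",
    "split_videos", "sample_clip_pair",
]

VALID_ACTIONS = (NORMAL, PROTECTIVE)


class AvaValidationError(ValueError):
    """A row or record violates the annotation contract."""


@dataclass(frozen=True)
class AvaRecord:
    """One annotated box on one keyframe."""

    video_id: str
    timestamp: int
    box: tuple[float, float, float, float]  # (x1, y1, x2, y2) in [0, 1]
    action_id: int
    entity_id: int

    def validate(self) -> "AvaRecord":
        x1, y1, x2, y2 = self.box
        if not (0.0 <= x1 < x2 <= 1.0 and 0.0 <= y1 < y2 <= 1.0):
            raise AvaValidationError(
                f"invalid box {self.box} for video {self.video_id!r} "
                f"t={self.timestamp}: need 0 <= x1 < x2 <= 1 and 0 <= y1 < y2 <= 1")
        if self.action_id not in VALID_ACTIONS:
            raise AvaValidationError(
                f"action_id {self.action_id} not in {VALID_ACTIONS}")
        if self.timestamp < 0:
            raise AvaValidationError(f"negative timestamp {self.timestamp}")
        return self


@dataclass(frozen=True)
class SplitSpec:
    """Video-level train/test split: seeded shuffle at a fixed ratio."""

    ratio: float = 0.8
    seed: int = 0
    stratify_by_protective: bool = False

    def __post_init__(self):
        if not 0.0 < self.ratio < 1.0:
            raise ValueError("ratio must lie strictly between 0 and 1")


@dataclass
class ClipPair:
    """Aligned slow/fast frame stacks for one keyframe window."""

    slow_frames: np.ndarray  # [T_slow, H, W, C] or [T_slow, H, W]
    fast_frames: np.ndarray  # [alpha * T_slow, ...]
    keyframe_timestamp: int
    source_video: str

    def __post_init__(self):
        if self.slow_frames.shape[1:] != self.fast_frames.shape[1:]:
            raise ValueError("slow and fast stacks must share spatial dims")

    @property
    def alpha(self) -> int:
        t_slow, t_fast = len(self.slow_frames), len(self.fast_frames)
        if t_fast % t_slow:
            raise ValueError("T_fast is not an integer multiple of T_slow")
        return t_fast // t_slow


# --------------------------------------------------------------------- I/O
def _format_coord(v: float) -> str:
    return f"{v:.6f}"


def read_ava_csv(path) -> list[AvaRecord]:
    """Parse a headerless AVA-style CSV; raises on any malformed row."""
    records: list[AvaRecord] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            if len(row) < 7:
                raise AvaValidationError(
                    f"{path}: line {lineno}: expected >= 7 fields, got {len(row)}")
            try:
                rec = AvaRecord(
                    video_id=row[0],
                    timestamp=int(row[1]),
                    box=tuple(float(v) for v in row[2:6]),
                    action_id=int(row[6]),
                    entity_id=int(row[7]) if len(row) > 7 else 0,
                )
            except ValueError as exc:
                if isinstance(exc, AvaValidationError):
                    raise
                raise AvaValidationError(
                    f"{path}: line {lineno}: malformed row: {exc}") from exc
            try:
                rec.validate()
            except AvaValidationError as exc:
                raise AvaValidationError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_ava_csv(records: Iterable[AvaRecord], path) -> None:
    """Write records in the canonical column order, re-readable losslessly."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for rec in records:
            rec.validate()
            writer.writerow([
                rec.video_id, rec.timestamp,
                *(_format_coord(v) for v in rec.box),
                rec.action_id, rec.entity_id,
            ])


# ----------------------------------------------------------- VIA conversion
def convert_via_to_ava(via_csv, fps: float, class_map: dict[str, int],
                       ) -> tuple[list[AvaRecord], int]:
    """Convert a VIA 2.x region-export CSV to AVA records.

    Expects the standard VIA export columns including ``filename``,
    ``region_shape_attributes`` (JSON with a rect) and
    ``region_attributes`` (JSON with a behavior label).  Frame geometry is
    read from ``file_attributes`` keys ``width``/``height`` when present,
    else from region metadata; frame indices are parsed from a trailing
    ``_<frame>`` in the filename stem and mapped to integer seconds via
    ``fps``.  Non-rectangle regions are skipped; the count of skipped
    regions is returned alongside the records.
    """
    records: list[AvaRecord] = []
    skipped = 0
    with open(via_csv, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            shape = json.loads(row.get("region_shape_attributes") or "{}")
            if not shape:
                continue
            if shape.get("name") != "rect":
                skipped += 1
                continue
            attrs = json.loads(row.get("region_attributes") or "{}")
            label = attrs.get("behavior") or attrs.get("label")
            if label not in class_map:
                raise AvaValidationError(
                    f"{via_csv}: line {lineno}: unknown behavior label {label!r}; "
                    f"known labels: {sorted(class_map)}")
            fattrs = json.loads(row.get("file_attributes") or "{}")
            width = float(fattrs.get("width", 1280))
            height = float(fattrs.get("height", 720))
            stem = row["filename"].rsplit(".", 1)[0]
            frame_idx = int(stem.rsplit("_", 1)[-1])
            video_id = stem.rsplit("_", 1)[0]
            x, y = float(shape["x"]), float(shape["y"])
            w, h = float(shape["width"]), float(shape["height"])
            rec = AvaRecord(
                video_id=video_id,
                timestamp=int(frame_idx / fps),
                box=(x / width, y / height, (x + w) / width, (y + h) / height),
                action_id=class_map[label],
                entity_id=int(attrs.get("entity_id", 0)),
            ).validate()
            records.append(rec)
    return records, skipped


# ------------------------------------------------------------------- split
def split_videos(video_ids: Sequence[str], spec: SplitSpec,
                 protective_videos: set[str] | None = None,
                 ) -> tuple[list[str], list[str]]:
    """Deterministic video-level partition with |train| = round(ratio * n).

    With ``stratify_by_protective`` and a non-empty ``protective_videos``
    set, the shuffle is retried with derived seeds until both splits contain
    at least one protective-bearing video (possible only when the set has
    >= 2 members spanning both sides).
    """
    ids = list(video_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("video ids must be unique")
    if len(ids) < 2:
        raise ValueError("need at least 2 videos to split")
    n_train = int(round(spec.ratio * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)

    def shuffle(seed: int) -> tuple[list[str], list[str]]:
        order = np.random.default_rng(seed).permutation(len(ids))
        shuffled = [ids[i] for i in order]
        return shuffled[:n_train], shuffled[n_train:]

    train, test = shuffle(spec.seed)
    if spec.stratify_by_protective and protective_videos:
        prot = set(protective_videos)
        if len(prot & set(ids)) >= 2:
            attempt = 0
            while not (prot & set(train) and prot & set(test)) and attempt < 1000:
                attempt += 1
                train, test = shuffle(spec.seed + 100_003 * attempt)
    return train, test


# -------------------------------------------------------------- clip cutting
def sample_clip_pair(frames: np.ndarray, keyframe_timestamp: int,
                     tau: int, alpha: int, fps: float, t_slow: int = 8,
                     source_video: str = "") -> ClipPair:
    """Cut the (slow, fast) stacks for one keyframe.

    A raw window of ``tau * t_slow`` frames is centered on the keyframe;
    indices beyond the sequence are clamped to the first/last frame (edge
    replication), so stack lengths are invariant to boundary effects.
    """
    frames = np.asarray(frames)
    if len(frames) == 0:
        raise ValueError("empty frame sequence")
    if tau < 1 or alpha < 1:
        raise ValueError("tau and alpha must be >= 1")
    if tau % alpha:
        raise ValueError(f"tau ({tau}) must be divisible by alpha ({alpha})")
    window = tau * t_slow
    center = int(round(keyframe_timestamp * fps))
    start = center - window // 2
    fast_stride = tau // alpha
    fast_idx = start + fast_stride * np.arange(alpha * t_slow)
    slow_idx = start + tau * np.arange(t_slow)
    fast_idx = np.clip(fast_idx, 0, len(frames) - 1)
    slow_idx = np.clip(slow_idx, 0, len(frames) - 1)
    return ClipPair(
        slow_frames=frames[slow_idx].copy(),
        fast_frames=frames[fast_idx].copy(),
        keyframe_timestamp=int(keyframe_timestamp),
        source_video=source_video,
    )
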