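"""End-to-end training, evaluation and inference over frame-directory
datasets with AVA-style annotations.

The model is backbone -> (optional) adaptive fusion -> detection head; the
loader cuts dual-rate clip pairs around annotated keyframes, applies
timing-aware minority oversampling and protective-class augmentation in
training mode, and feeds candidate boxes (ground truth here; a detector at
deployment) to the head.  Optimization is gradient descent with momentum at
a constant learning rate.  All randomness derives from the run seed, so a
repeated run reproduces the loss trajectory exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import PROTECTIVE, nn
from .backbone import build_backbone
from .config import RunConfig
from .data_ava import AvaRecord, ClipPair, read_ava_csv, sample_clip_pair
from .evaluation import ResultRecord, evaluate_detections, write_result_csv
from .fusion import BAF
from .head import MPBHead
from .losses import make_loss
from .nn import Tensor
from .nn import functional as F
from .sampler import (augment_protective, build_minority_pool,
                      oversample_batch, preprocess)

__all__ = ["ProtectiveBehaviorModel", "KeyframeDataset", "TrainState",
           "train", "evaluate", "infer", "save_checkpoint", "load_checkpoint"]

log = logging.getLogger("cattleact")

CHECKPOINT_VERSION = 1


class ProtectiveBehaviorModel(nn.Module):
    """Backbone + adaptive fusion + balanced head, end to end."""

    def __init__(self, cfg: RunConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.backbone = build_backbone(cfg.backbone, rng=rng)
        c_slow, c_fast = self.backbone.out_channels
        self.baf = BAF(c_slow, c_fast, rng=rng) if cfg.enable_baf else None
        self.head = MPBHead(c_slow, c_fast, cfg.head, rng=rng)

    def forward(self, slow: Tensor, fast: Tensor, boxes: np.ndarray,
                batch_index: np.ndarray) -> Tensor:
        feats = self.backbone(slow, fast)
        slow_feat = feats.slow
        if self.baf is not None:
            slow_feat = self.baf(slow_feat, feats.fast)
        return self.head(slow_feat, feats.fast, boxes, batch_index)


# ------------------------------------------------------------------ dataset
class KeyframeDataset:
    """Annotated keyframes of a frame-directory dataset.

    Groups records by (video_id, timestamp) and cuts preprocessed clip
    pairs on demand, with a small per-video frame cache.
    """

    def __init__(self, frames_root, csv_path, cfg: RunConfig):
        self.frames_root = Path(frames_root)
        self.records = read_ava_csv(csv_path)
        self.cfg = cfg
        self.by_key: dict[tuple, list[AvaRecord]] = {}
        for r in self.records:
            self.by_key.setdefault((r.video_id, r.timestamp), []).append(r)
        self.keys = sorted(self.by_key)
        self.pool = build_minority_pool(self.records)
        self._cache: dict[str, np.ndarray] = {}

    def __len__(self):
        return len(self.keys)

    def frames_for(self, video_id: str) -> np.ndarray:
        if video_id not in self._cache:
            import imageio.v3 as iio

            vdir = self.frames_root / video_id
            files = sorted(vdir.glob("*.png"))
            if not files:
                raise FileNotFoundError(f"no frames under {vdir}")
            if len(self._cache) > 16:
                self._cache.clear()
            self._cache[video_id] = np.stack([iio.imread(f) for f in files])
        return self._cache[video_id]

    def clip(self, key: tuple, train_mode: bool,
             rng: np.random.Generator | None = None) -> ClipPair:
        video_id, timestamp = key
        bcfg = self.cfg.backbone
        clip = sample_clip_pair(
            self.frames_for(video_id), timestamp, bcfg.tau, bcfg.alpha,
            self.cfg.data.fps, t_slow=bcfg.t_slow, source_video=video_id)
        labels = [r.action_id for r in self.by_key[key]]
        if train_mode and PROTECTIVE in labels:
            clip = augment_protective(clip, self.cfg.augment, rng)
        return preprocess(clip, self.cfg.data.target_size, train_mode, rng,
                          pca_jitter_scale=self.cfg.augment.pca_jitter_scale
                          if train_mode else 0.0)

    def batch_arrays(self, keys: list[tuple], train_mode: bool,
                     rng: np.random.Generator | None = None):
        """Stack clips into model tensors plus flat boxes/labels/index."""
        slows, fasts, boxes, labels, index = [], [], [], [], []
        for b, key in enumerate(keys):
            clip = self.clip(key, train_mode, rng)
            slows.append(clip.slow_frames.transpose(3, 0, 1, 2))
            fasts.append(clip.fast_frames.transpose(3, 0, 1, 2))
            for r in self.by_key[key]:
                boxes.append(r.box)
                labels.append(r.action_id)
                index.append(b)
        return (Tensor(np.stack(slows)), Tensor(np.stack(fasts)),
                np.asarray(boxes, dtype=np.float64),
                np.asarray(labels), np.asarray(index, dtype=np.intp))


# ----------------------------------------------------------------- training
@dataclass
class TrainState:
    epoch: int = 0
    global_step: int = 0
    best_val_map: float = -1.0
    best_epoch: int = -1
    history: list = field(default_factory=list)


def save_checkpoint(path, model: ProtectiveBehaviorModel, state: TrainState,
                    optimizer: nn.SGD | None = None) -> None:
    payload = {f"model/{k}": v for k, v in model.state_dict().items()}
    if optimizer is not None:
        for i, v in enumerate(optimizer.state_dict()["velocity"]):
            payload[f"optim/velocity/{i}"] = v
    payload["meta"] = np.frombuffer(json.dumps({
        "version": CHECKPOINT_VERSION,
        "config": model.cfg.to_dict(),
        "epoch": state.epoch,
        "global_step": state.global_step,
        "best_val_map": state.best_val_map,
        "best_epoch": state.best_epoch,
    }).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[ProtectiveBehaviorModel, TrainState, dict]:
    archive = np.load(path, allow_pickle=False)
    meta = json.loads(bytes(archive["meta"]))
    if meta["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['version']}")
    cfg = RunConfig.from_dict(meta["config"])
    model = ProtectiveBehaviorModel(cfg)
    model.load_state_dict({k[len("model/"):]: archive[k]
                           for k in archive.files if k.startswith("model/")})
    state = TrainState(epoch=meta["epoch"], global_step=meta["global_step"],
                       best_val_map=meta["best_val_map"],
                       best_epoch=meta["best_epoch"])
    velocity = [archive[k] for k in sorted(
        (k for k in archive.files if k.startswith("optim/velocity/")),
        key=lambda k: int(k.rsplit("/", 1)[1]))]
    return model, state, {"velocity": velocity}


def _epoch_batches(keys: list, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(len(keys))
    for lo in range(0, len(order), batch_size):
        yield [keys[i] for i in order[lo:lo + batch_size]]


def train(cfg: RunConfig, data_dir, out_dir=None,
          val_split: str = "test") -> TrainState:
    """Momentum-descent training with per-epoch validation mAP.

    ``data_dir`` must hold frames/ plus train.csv and <val_split>.csv.
    Returns the final TrainState; the best checkpoint (highest validation
    mAP, earliest epoch on ties) is written to out_dir when given.
    """
    data_dir = Path(data_dir)
    train_ds = KeyframeDataset(data_dir / "frames", data_dir / "train.csv", cfg)
    val_csv = data_dir / f"{val_split}.csv"
    val_ds = (KeyframeDataset(data_dir / "frames", val_csv, cfg)
              if val_csv.exists() else None)
    if len(train_ds) == 0:
        raise ValueError("training split is empty")

    seed_seq = np.random.SeedSequence(cfg.seed)
    model_rng, loader_rng, over_rng, aug_rng = (
        np.random.default_rng(s) for s in seed_seq.spawn(4))
    model = ProtectiveBehaviorModel(cfg, rng=model_rng)
    optimizer = nn.SGD(model.parameters(), lr=cfg.optimizer.learning_rate,
                       momentum=cfg.optimizer.momentum,
                       weight_decay=cfg.optimizer.weight_decay)
    loss_fn = make_loss(cfg.loss_name, cfg.loss)
    state = TrainState()
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(cfg.optimizer.max_epochs):
        if cfg.optimizer.lr_schedule == "cosine":
            optimizer.lr = cfg.optimizer.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * epoch / cfg.optimizer.max_epochs))
        model.train()
        epoch_losses = []
        for batch_keys in _epoch_batches(train_ds.keys,
                                         cfg.optimizer.batch_size, loader_rng):
            batch_keys = oversample_batch(batch_keys, train_ds.pool,
                                          cfg.oversample, over_rng)
            slow, fast, boxes, labels, index = train_ds.batch_arrays(
                batch_keys, train_mode=True, rng=aug_rng)
            probs = model(slow, fast, boxes, index)
            p_y = F.gather_rows(probs, labels - 1)  # labels are 1-based
            loss, breakdown = loss_fn(p_y, labels)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"loss diverged (non-finite) at step {state.global_step}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            state.global_step += 1
            epoch_losses.append(loss.item())
            if breakdown is not None:
                log.info("step=%d L_F=%.4f L_WCE=%.4f focal_weight=%.3f "
                         "L_DFL=%.4f", state.global_step,
                         breakdown.l_f.item(), breakdown.l_wce.item(),
                         breakdown.focal_weight, breakdown.l_dfl.item())
        state.epoch = epoch + 1
        entry = {"epoch": state.epoch,
                 "train_loss": float(np.mean(epoch_losses))}
        if val_ds is not None and len(val_ds):
            report = _evaluate_dataset(model, val_ds)
            entry["val_map"] = report["map"]
            if report["map"] > state.best_val_map:
                state.best_val_map = report["map"]
                state.best_epoch = state.epoch
                if out_dir:
                    save_checkpoint(out_dir / "best.npz", model, state,
                                    optimizer)
        state.history.append(entry)
        log.info("epoch=%d train_loss=%.4f val_map=%s", state.epoch,
                 entry["train_loss"], entry.get("val_map"))
    if out_dir:
        save_checkpoint(out_dir / "last.npz", model, state, optimizer)
        (out_dir / "history.json").write_text(json.dumps(state.history))
    state.model = model  # convenience for in-process callers
    return state


# --------------------------------------------------------------- evaluation
def _detections_for_dataset(model: ProtectiveBehaviorModel,
                            ds: KeyframeDataset) -> list[ResultRecord]:
    """Classify every annotated box; emit one scored row per class per box
    (the ranking convention AP integration expects)."""
    model.eval()
    out: list[ResultRecord] = []
    with nn.no_grad():
        for key in ds.keys:
            slow, fast, boxes, _, index = ds.batch_arrays([key], False)
            if len(boxes) == 0:
                continue
            probs = model(slow, fast, boxes, index)
            for box, p in zip(boxes, probs.data):
                for c, score in enumerate(p, start=1):
                    out.append(ResultRecord(key[0], key[1], tuple(box), c,
                                            float(score)))
    return out


def _evaluate_dataset(model, ds: KeyframeDataset) -> dict:
    return evaluate_detections(_detections_for_dataset(model, ds), ds.records)


def evaluate(checkpoint, data_dir, split: str = "test",
             out_dir=None) -> dict:
    """Deterministic evaluation of a checkpoint against an annotated split."""
    model, _, _ = load_checkpoint(checkpoint)
    data_dir = Path(data_dir)
    ds = KeyframeDataset(data_dir / "frames", data_dir / f"{split}.csv",
                         model.cfg)
    dets = _detections_for_dataset(model, ds)
    report = evaluate_detections(dets, ds.records)
    if out_dir:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_result_csv(dets, out_dir / f"results_{split}.csv")
        (out_dir / f"report_{split}.json").write_text(json.dumps(report, indent=2))
    return report


def infer(checkpoint, frames: np.ndarray, boxes_per_keyframe: dict,
          video_id: str = "video", fps: float | None = None,
          ) -> list[ResultRecord]:
    """Label supplied boxes on each keyframe of one video.

    ``boxes_per_keyframe`` maps integer second -> list of normalized boxes;
    keyframes without boxes are skipped with a warning.  Each box yields one
    row carrying its argmax class and confidence.
    """
    model, _, _ = load_checkpoint(checkpoint)
    model.eval()
    cfg = model.cfg
    fps = fps if fps is not None else cfg.data.fps
    results: list[ResultRecord] = []
    with nn.no_grad():
        for timestamp in sorted(boxes_per_keyframe):
            boxes = np.asarray(boxes_per_keyframe[timestamp],
                               dtype=np.float64).reshape(-1, 4)
            if len(boxes) == 0:
                log.warning("keyframe %s has no boxes; skipped", timestamp)
                continue
            clip = sample_clip_pair(frames, timestamp, cfg.backbone.tau,
                                    cfg.backbone.alpha, fps,
                                    t_slow=cfg.backbone.t_slow,
                                    source_video=video_id)
            clip = preprocess(clip, cfg.data.target_size, train_mode=False)
            slow = Tensor(clip.slow_frames.transpose(3, 0, 1, 2)[None])
            fast = Tensor(clip.fast_frames.transpose(3, 0, 1, 2)[None])
            dets = model.head.detect(
                *_fused_features(model, slow, fast), boxes,
                np.zeros(len(boxes), dtype=np.intp))
            for det in dets:
                results.append(ResultRecord(video_id, timestamp, det.box,
                                            det.label, det.confidence))
    return results


def _fused_features(model: ProtectiveBehaviorModel, slow, fast):
    feats = model.backbone(slow, fast)
    slow_feat = feats.slow
    if model.baf is not None:
        slow_feat = model.baf(slow_feat, feats.fast)
    return slow_feat, feats.fast
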