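"""Multi-path balanced detection head for class-imbalanced box classification.

The head consumes the final slow and fast feature maps plus candidate boxes
(ground-truth or detector-supplied; the head never regresses boxes).  Both
maps are temporally mean-pooled to a single frame, per-box region features
are sampled bilinearly on each, spatially max-pooled to vectors, and
concatenated to width C_slow + C_fast.  A sigmoid bottleneck gate
recalibrates channels, and a two-layer MLP produces logits that are
calibrated before the softmax:

    z' = z / T + b

with temperature T > 0 softening the distribution (tempering majority-class
overconfidence) and a learnable per-class bias b shifting the decision
boundary toward sparsely sampled classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn import functional as F

__all__ = ["HeadConfig", "Detection", "MPBHead", "calibrate_logits"]


@dataclass(frozen=True)
class HeadConfig:
    hidden_dim: int = 512
    temperature_T: float = 2.0
    dropout: float = 0.5
    roi_resolution: int = 7
    num_classes: int = 2
    norm: str = "batch"  # "batch" (reference protocol) or "layer" (small batches)

    def __post_init__(self):
        if self.temperature_T <= 0:
            raise ValueError("temperature must be positive")
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be at least 1")
        if self.norm not in ("batch", "layer"):
            raise ValueError("norm must be 'batch' or 'layer'")


@dataclass
class Detection:
    """One classified box: probabilities on the simplex, argmax label."""

    box: tuple[float, float, float, float]
    probs: np.ndarray
    label: int            # class code (1-based, matching annotation ids)
    confidence: float


def calibrate_logits(z: Tensor, temperature: float, bias: Tensor) -> Tensor:
    """Temperature-and-bias calibration z' = z / T + b (rowwise)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return z * (1.0 / temperature) + bias


class MPBHead(nn.Module):
    def __init__(self, c_slow: int, c_fast: int, cfg: HeadConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        self.c_total = c_slow + c_fast
        mid = max(self.c_total // 4, 1)
        norm1d = nn.LayerNorm1d if cfg.norm == "layer" else nn.BatchNorm1d
        # channel recalibration bottleneck (pointwise layers on [N, C])
        self.gate_fc1 = nn.Linear(self.c_total, mid, rng=rng)
        self.gate_bn = norm1d(mid)
        self.gate_fc2 = nn.Linear(mid, self.c_total, rng=rng)
        # dual-balanced classifier
        self.fc1 = nn.Linear(self.c_total, cfg.hidden_dim, rng=rng)
        self.bn1 = norm1d(cfg.hidden_dim)
        self.drop1 = nn.Dropout(cfg.dropout, rng=np.random.default_rng(
            int(rng.integers(2**31))))
        self.drop2 = nn.Dropout(cfg.dropout, rng=np.random.default_rng(
            int(rng.integers(2**31))))
        self.fc2 = nn.Linear(cfg.hidden_dim, cfg.num_classes, rng=rng)
        self.class_bias = nn.Parameter(np.zeros(cfg.num_classes))

    # ----------------------------------------------------------------- stages
    def pool_and_extract(self, slow_feat: Tensor, fast_feat: Tensor,
                         boxes: np.ndarray,
                         batch_index: np.ndarray | None = None) -> Tensor:
        """Temporal mean pooling + per-box bilinear region pooling on both
        pathways; returns the concatenated [N, C_slow + C_fast] matrix."""
        boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
        n = boxes.shape[0]
        if batch_index is None:
            batch_index = np.zeros(n, dtype=np.intp)
        if n == 0:
            return Tensor(np.zeros((0, self.c_total)))
        r = self.cfg.roi_resolution
        parts = []
        for fmap in (slow_feat, fast_feat):
            pooled = fmap.mean(axis=2)  # [B, C, H, W]
            roi = F.roi_pool_bilinear(pooled, boxes, batch_index, r)
            vec = roi.reshape(n, fmap.shape[1], r * r).max(axis=2)
            parts.append(vec)
        return nn.concatenate(parts, axis=1)

    def channel_recalibrate(self, features: Tensor) -> Tensor:
        gate = self.gate_fc2(
            self.gate_bn(self.gate_fc1(features)).relu()).sigmoid()
        self.last_gate = gate
        return features * gate

    def classify(self, features: Tensor) -> Tensor:
        """MLP -> calibration -> softmax; rows live on the simplex."""
        h = self.drop1(self.bn1(self.fc1(features)).relu())
        z = self.fc2(self.drop2(h))
        z = calibrate_logits(z, self.cfg.temperature_T, self.class_bias)
        return z.softmax(axis=1)

    def forward(self, slow_feat: Tensor, fast_feat: Tensor, boxes: np.ndarray,
                batch_index: np.ndarray | None = None) -> Tensor:
        feats = self.pool_and_extract(slow_feat, fast_feat, boxes, batch_index)
        if feats.shape[0] == 0:
            return feats
        return self.classify(self.channel_recalibrate(feats))

    def detect(self, slow_feat: Tensor, fast_feat: Tensor, boxes: np.ndarray,
               batch_index: np.ndarray | None = None) -> list[Detection]:
        probs = self.forward(slow_feat, fast_feat, boxes, batch_index)
        out = []
        for box, p in zip(np.asarray(boxes).reshape(-1, 4), probs.data):
            label = int(np.argmax(p)) + 1  # class codes are 1-based
            out.append(Detection(tuple(box), p.copy(), label, float(p.max())))
        return out
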