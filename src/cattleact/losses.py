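"""Loss family for imbalanced two-class behavior detection.

All losses operate on the per-sample probability of the *true* class,
``p_y`` (the softmax output gathered at the label), with integer labels
1 = normal, 2 = protective.

  focal            L_F   = mean( -a_y (1 - p_y)^gamma log p_y )
  weighted CE      L_WCE = mean( -w_y log p_y )
  dual focus       L_DFL = fw * L_F + (1 - fw) * L_WCE,
                   fw    = clip( L_WCE / (L_WCE + L_F), 0.3, 0.7 )

The mixing weight fw is recomputed every batch from gradient-detached loss
values: it is a weighting *schedule* (raise the focal share when weighted CE
is the larger, i.e. confidence is low; fall back toward weighted CE when
hard-example mining dominates), not a quantity to optimize through, and its
clipping bounds keep either term from being silenced by an outlier batch.
The balance factor a_y defaults to per-class form — alpha for protective,
(1 - alpha) for normal — with a symmetric variant (alpha for every sample)
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import NORMAL, PROTECTIVE
from .nn import Tensor, as_tensor

__all__ = [
    "LossConfig", "LossBreakdown",
    "bce_loss", "focal_loss", "weighted_ce", "dual_focus_loss",
    "make_loss", "LOSS_GRID", "default_loss_config",
]

_EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    alpha_focal: float = 0.8
    gamma: float = 2.0
    class_weights: tuple[float, float] = (1.0, 2.0)  # (normal, protective)
    clip_lo: float = 0.3
    clip_hi: float = 0.7
    alpha_per_class: bool = True
    reduction: str = "mean"

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be positive")
        if not 0.0 <= self.clip_lo <= self.clip_hi <= 1.0:
            raise ValueError("need 0 <= clip_lo <= clip_hi <= 1")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")

    def weight_for(self, label: int) -> float:
        if label == NORMAL:
            return self.class_weights[0]
        if label == PROTECTIVE:
            return self.class_weights[1]
        raise KeyError(f"no class weight configured for label {label}")


@dataclass
class LossBreakdown:
    """Per-batch components of the dual loss, for logging and tests."""

    l_f: Tensor
    l_wce: Tensor
    focal_weight: float
    l_dfl: Tensor


def _check_probs(p: Tensor):
    if (p.data < 0).any() or (p.data > 1).any():
        raise ValueError("true-class probabilities must lie in [0, 1]")


def _reduce(x: Tensor, reduction: str) -> Tensor:
    return x.mean() if reduction == "mean" else x.sum()


def _log_floored(p: Tensor) -> Tensor:
    return p.clip(_EPS, 1.0).log()


def _alpha_factors(cfg: LossConfig, labels, n: int) -> np.ndarray:
    if not cfg.alpha_per_class or labels is None:
        return np.full(n, cfg.alpha_focal)
    labels = np.asarray(labels)
    return np.where(labels == PROTECTIVE, cfg.alpha_focal,
                    1.0 - cfg.alpha_focal)


def bce_loss(p_y, cfg: LossConfig | None = None) -> Tensor:
    """Plain cross-entropy on the true-class probability."""
    p = as_tensor(p_y)
    _check_probs(p)
    red = cfg.reduction if cfg else "mean"
    return _reduce(-_log_floored(p), red)


def focal_loss(p_y, cfg: LossConfig, labels=None) -> Tensor:
    """Hard-example-weighted cross-entropy; reduces to plain CE at
    gamma=0, alpha=1 (symmetric)."""
    p = as_tensor(p_y)
    _check_probs(p)
    a = Tensor(_alpha_factors(cfg, labels, p.data.size).reshape(p.shape))
    per_sample = -1.0 * a * (1.0 - p) ** cfg.gamma * _log_floored(p)
    return _reduce(per_sample, cfg.reduction)


def weighted_ce(p_y, labels, cfg: LossConfig) -> Tensor:
    """Cross-entropy with per-class weights w_y."""
    p = as_tensor(p_y)
    _check_probs(p)
    w = Tensor(np.array([cfg.weight_for(int(y)) for y in np.asarray(labels)],
                        dtype=np.float64).reshape(p.shape))
    return _reduce(-1.0 * w * _log_floored(p), cfg.reduction)


def dual_focus_loss(p_y, labels, cfg: LossConfig) -> LossBreakdown:
    """Adaptive convex combination of focal loss and weighted CE."""
    p = as_tensor(p_y)
    if p.data.size == 0:
        raise ValueError("batch must be nonempty")
    l_f = focal_loss(p, cfg, labels)
    l_wce = weighted_ce(p, labels, cfg)
    total = l_f.item() + l_wce.item()  # detached batch statistics
    if total == 0.0:
        fw = 0.5
    else:
        fw = float(np.clip(l_wce.item() / total, cfg.clip_lo, cfg.clip_hi))
    l_dfl = l_f * fw + l_wce * (1.0 - fw)
    return LossBreakdown(l_f=l_f, l_wce=l_wce, focal_weight=fw, l_dfl=l_dfl)


def make_loss(name: str, cfg: LossConfig):
    """Factory for the configurable loss surface: bce | focal | wce | dfl.

    Returns ``fn(p_y, labels) -> (loss Tensor, LossBreakdown | None)``.
    """
    name = name.lower()
    if name == "bce":
        return lambda p, y: (bce_loss(p, cfg), None)
    if name == "focal":
        return lambda p, y: (focal_loss(p, cfg, y), None)
    if name == "wce":
        return lambda p, y: (weighted_ce(p, y, cfg), None)
    if name == "dfl":
        def fn(p, y):
            bd = dual_focus_loss(p, y, cfg)
            return bd.l_dfl, bd
        return fn
    raise ValueError(f"unknown loss {name!r}; choose bce, focal, wce or dfl")


# hyperparameter grid shipped as named presets: (alpha, gamma, w_protective)
# with w_normal = 1; the first entry is the best-performing configuration
# and the package default.
LOSS_GRID: dict[str, LossConfig] = {
    "a0.8_g2.0_w1:2": LossConfig(0.8, 2.0, (1.0, 2.0)),
    "a0.6_g2.0_w1:4": LossConfig(0.6, 2.0, (1.0, 4.0)),
    "a0.6_g3.0_w1:4": LossConfig(0.6, 3.0, (1.0, 4.0)),
    "a0.8_g2.0_w1:4": LossConfig(0.8, 2.0, (1.0, 4.0)),
    "a0.8_g3.0_w1:4": LossConfig(0.8, 3.0, (1.0, 4.0)),
    "a0.6_g2.0_w1:2": LossConfig(0.6, 2.0, (1.0, 2.0)),
    "a0.6_g3.0_w1:2": LossConfig(0.6, 3.0, (1.0, 2.0)),
    "a0.8_g3.0_w1:2": LossConfig(0.8, 3.0, (1.0, 2.0)),
}


def default_loss_config() -> LossConfig:
    return LOSS_GRID["a0.8_g2.0_w1:2"]
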