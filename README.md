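# cattleact

Spatio-temporal detection of **protective behavior in dairy cattle** —
tail-swaying, head-shaking, ear-flapping and leg-kicking, the brief
high-frequency appendage motions cattle use against mosquitoes and other
irritants.  These actions are welfare indicators: their frequency rises
with pain and stress, so detecting them automatically from barn video
supports early intervention.  The package is written for researchers in
precision livestock farming and for anyone who needs a fully inspectable,
CPU-runnable reference implementation of a dual-rate attention video
detector with class-imbalance handling.

## The model

Given a clip and candidate animal boxes on 1 Hz keyframes, each box is
classified as *normal* or *protective* (the classes are mutually
exclusive).  The architecture is a SlowFast-style dual-pathway 3D ResNet
extended with multi-stage attention:

- **Dual-rate backbone** parameterized by (τ, α, β) = (8, 4, 1/8): the
  slow pathway samples every τ-th frame at full width; the fast pathway
  runs α× faster at β× the channel width.  Lateral *FastToSlow* fusion
  (time-strided `[5,1,1]` convolution, channel compression r = 0.5,
  ST-CBAM gating, element-wise addition) follows the stem and res2–res4.
- **ST-CBAM**: sequential channel → spatial → temporal → joint
  spatio-temporal attention over `X ∈ R^{B×C×T×H×W}`, with gates
  `Y_c = X·A_c`, `Y_s = Y_c·A_s`, `Y_t = Y_s·A_t` and a final residual
  `Y = X + Y_t·A_st`.  Inserted after every residual block of res3/res4.
- **BAF** (bidirectional adaptive fusion) before the head: projection to
  half the slow width, `[3,1,1]` motion enhancement, softmax path weights
  `F_att = F'_s·A_s + F'_f·A_f` with `A_s + A_f = 1`, a 3×3×3 fusion
  convolution, and a learnable residual `F_out = F_s + F_fusion·α_res`
  (α_res initialized at 0.1).
- **MPBHead**: temporal pooling, per-box region features from both paths
  (concatenated width `C_slow + C_fast`), a sigmoid channel-recalibration
  bottleneck, and an MLP whose logits are calibrated as **`z' = z/T + b`**
  (temperature `T` plus learnable class bias `b`) before the softmax.
- **Dual Focus Loss**:
  `L_DFL = fw·L_F + (1 − fw)·L_WCE` with
  `fw = clip(L_WCE/(L_WCE + L_F), 0.3, 0.7)` recomputed per batch from
  detached values; `L_F = −α(1−p_y)^γ log p_y` (focal) and
  `L_WCE = −w_y log p_y` (weighted cross-entropy).  The shipped grid
  crosses α ∈ {0.6, 0.8}, γ ∈ {2, 3}, w = 1:2 / 1:4; default (0.8, 2, 1:2).
- **Timing-aware oversampling**: before each training batch, with
  probability p the batch's keyframe indices are replaced by draws from
  the precomputed pool of protective keyframes (real keyframes, so clip
  timing stays valid), and protective clips get targeted augmentation
  (color jitter 50%, color enhancement 70%, random occlusion 30%).
- **Evaluation**: mAP at IoU 0.5 — greedy confidence-ordered class-wise
  matching per keyframe, all-point precision-envelope AP, unweighted mean
  over the two classes.

Everything runs on a built-in NumPy reverse-mode autodiff engine
(`cattleact.nn`), so the full pipeline — training included — works on a
plain CPU with no accelerator stack.  A deterministic synthetic-video
generator (`cattleact.synthetic`) emulates the structure of the real data
(one animal body with an appendage whose oscillation rate distinguishes
the classes, ~12% protective fraction) so every component is exercisable
without any download.

## Worked example

Generate a synthetic dataset, train the CPU-scale preset, evaluate:

```bash
cattleact generate-data --out demo_data --n-videos 20 \
    --frames-per-video 16 --frame-size 48 --imbalance 0.2 --seed 42
cattleact train --data demo_data --out demo_run --seed 0
cattleact evaluate --checkpoint demo_run/best.npz --data demo_data
```

The same flow from Python, with the output it printed:

```python
>>> from cattleact.config import tiny_run_config
>>> from cattleact.synthetic import SyntheticSpec, generate_dataset
>>> from cattleact.pipeline import train, evaluate
>>> spec = SyntheticSpec(n_videos=20, frames_per_video=16, fps=8,
...                      frame_size=(48, 48), imbalance=0.2, seed=42)
>>> m = generate_dataset(spec, "demo_data")
>>> len(m["train_videos"]), len(m["test_videos"]), len(m["protective_videos"])
(16, 4, 4)
>>> cfg = tiny_run_config(seed=0, max_epochs=12, lr_schedule="cosine")
>>> state = train(cfg, "demo_data", out_dir="demo_run")
>>> round(state.best_val_map, 3), state.best_epoch
(0.851, 11)
>>> evaluate("demo_run/best.npz", "demo_data", "test")
{'iou_threshold': 0.5,
 'ap_per_class': {'normal': 0.75, 'protective': 0.9523809523809523},
 'map': 0.8511904761904762}
```

Reading the numbers: the 20 synthetic videos split 16 train / 4 test at
the video level, 4 of them protective; the best checkpoint (epoch 11)
ranks protective test boxes almost perfectly (AP 0.952) and normal boxes
well (AP 0.75), giving mAP@0.5 = 0.851 on held-out videos after about
two minutes of CPU training.  On real farm video the task is far harder —
the synthetic corpus isolates the motion-rate cue the architecture is
designed for.

## Layout

| module | contents |
| --- | --- |
| `cattleact.nn` | NumPy autodiff engine: conv3d, pooling, normalization, SGD |
| `cattleact.data_ava` | AVA-style CSV I/O, VIA conversion, splits, clip cutting |
| `cattleact.sampler` | minority oversampling, protective augmentation, preprocessing |
| `cattleact.attention` | ST-CBAM (channel/spatial/temporal/joint gates) |
| `cattleact.backbone` | dual-rate 3D-ResNet with FastToSlow fusion |
| `cattleact.fusion` | BAF adaptive path mixing and residual injection |
| `cattleact.head` | MPBHead: ROI features, recalibration, calibrated classifier |
| `cattleact.losses` | BCE / focal / weighted CE / dual focus loss + presets |
| `cattleact.evaluation` | IoU, matching, AP, mAP@0.5, result CSV |
| `cattleact.synthetic` | deterministic synthetic video corpus |
| `cattleact.pipeline` | training loop, checkpoints, evaluation, inference |
| `cattleact.cli` | `cattleact generate-data / train / evaluate / infer` |

See `docs/methods.md` for modeling assumptions, parameter defaults, and
what the synthetic experiments do and do not demonstrate.
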