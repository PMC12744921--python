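"""The compound segmentation objective: Tversky plus weighted cross-entropy.

The Tversky index generalises Dice by weighting false positives with
``alpha`` and false negatives with ``beta``; ``alpha < beta`` trades
precision for recall, which matters clinically because missed lesion
voxels are worse than spurious ones.  On slices without any lesion the
Tversky term's gradient collapses towards zero, so a binary cross-entropy
term (weight ``lam``) is added to keep lesion-free slices informative.

Total loss:  L = L_Tversky + lam * L_BCE.

All functions accept either plain numpy arrays (returning a float) or
autodiff tensors (returning a scalar tensor on the tape).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import tensor as F
from .nn.tensor import Tensor, as_tensor

__all__ = ["LossConfig", "tversky_loss", "bce_loss", "combined_loss"]

_CLIP = 1e-7


@dataclass
class LossConfig:
    alpha: float = 0.3    # false-positive weight
    beta: float = 0.7     # false-negative weight
    lam: float = 0.6      # cross-entropy weight
    smooth: float = 1.0   # stabiliser added to numerator and denominator

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.lam < 0:
            raise ValueError("loss weights must be non-negative")
        if self.smooth <= 0:
            raise ValueError("smooth must be positive")


def _check_shapes(p, g):
    if p.shape != np.shape(g.data if isinstance(g, Tensor) else g):
        raise ValueError(f"shape mismatch: {p.shape} vs {np.shape(g)}")


def tversky_loss(pred, gt, cfg: LossConfig = LossConfig()):
    """1 - (TP + eps) / (TP + alpha*FP + beta*FN + eps) with soft counts."""
    if isinstance(pred, Tensor):
        g = Tensor(np.asarray(gt.data if isinstance(gt, Tensor) else gt,
                              dtype=np.float32))
        _check_shapes(pred, g)
        tp = F.tsum(F.mul(pred, g))
        fp = F.tsum(F.mul(pred, F.add(F.mul(g, -1.0), 1.0)))
        fn = F.tsum(F.mul(F.add(F.mul(pred, -1.0), 1.0), g))
        num = F.add(tp, cfg.smooth)
        den = F.add(F.add(tp, F.add(F.mul(fp, cfg.alpha), F.mul(fn, cfg.beta))),
                    cfg.smooth)
        return F.add(F.mul(F.div(num, den), -1.0), 1.0)
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(gt, dtype=np.float64)
    _check_shapes(p, g)
    tp = float((p * g).sum())
    fp = float((p * (1 - g)).sum())
    fn = float(((1 - p) * g).sum())
    return 1.0 - (tp + cfg.smooth) / (tp + cfg.alpha * fp + cfg.beta * fn + cfg.smooth)


def bce_loss(pred, gt):
    """Mean binary cross-entropy; predictions are clipped to avoid log(0)."""
    if isinstance(pred, Tensor):
        g = Tensor(np.asarray(gt.data if isinstance(gt, Tensor) else gt,
                              dtype=np.float32))
        _check_shapes(pred, g)
        pc = F.clip(pred, _CLIP, 1.0 - _CLIP)
        one_m_g = F.add(F.mul(g, -1.0), 1.0)
        one_m_p = F.add(F.mul(pc, -1.0), 1.0)
        ll = F.add(F.mul(g, F.log(pc)), F.mul(one_m_g, F.log(one_m_p)))
        return F.mul(F.tsum(ll), -1.0 / pred.size)
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(gt, dtype=np.float64)
    _check_shapes(p, g)
    pc = np.clip(p, _CLIP, 1.0 - _CLIP)
    return float(-(g * np.log(pc) + (1 - g) * np.log(1 - pc)).mean())


def combined_loss(pred, gt, cfg: LossConfig = LossConfig()):
    """Tversky term plus ``lam`` times the cross-entropy term."""
    t = tversky_loss(pred, gt, cfg)
    b = bce_loss(pred, gt)
    if isinstance(t, Tensor):
        return F.add(t, F.mul(b, cfg.lam))
    return t + cfg.lam * b
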