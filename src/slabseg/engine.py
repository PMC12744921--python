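"""Training loop, learning-rate schedule, sliding-stack inference and
cohort evaluation.

Training samples random (case, slice) pairs — half of them from slices
that contain lesion, half unrestricted — extracts the windowed ``k``-slice
stack, applies a shared random in-plane rotation to stack and mask, and
optimises the compound Tversky + cross-entropy objective with Adam under a
cosine-annealing schedule with warm restarts.  Inference slides the stack
over every slice of a volume and binarizes the central-slice probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .losses import LossConfig, combined_loss
from .metrics import CaseMetrics, CohortSummary, aggregate_ci, case_metrics
from .models import MixedNetConfig, MixedUNet, build_mixed_unet, count_parameters
from .nn.optim import Adam
from .phantom import CTVolume, MaskVolume
from .preprocessing import (SliceStack, WindowSpec, apply_window,
                            augment_rotate, extract_stack, normalize_stack)

__all__ = ["TrainConfig", "cosine_lr", "train", "predict_volume",
           "evaluate_cohort", "SegmentationModel", "SegmentationResults"]


@dataclass
class TrainConfig:
    lr0: float = 2e-4          # initial learning rate
    lr_min: float = 1e-6       # floor of the cosine schedule
    t0: int = 300              # iterations per restart cycle
    iterations: int = 600
    batch_size: int = 4
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    lesion_fraction: float = 0.5   # share of samples drawn from lesion slices
    augment: bool = True
    max_rotation_deg: float = 30.0
    threshold: float = 0.5

    def __post_init__(self):
        if self.lr_min >= self.lr0:
            raise ValueError("lr_min must be below lr0")
        if self.t0 < 1:
            raise ValueError("t0 must be >= 1")
        if self.iterations < 1 or self.batch_size < 1:
            raise ValueError("iterations and batch_size must be positive")


def cosine_lr(iteration: int, cfg: TrainConfig) -> float:
    """Cosine annealing with warm restarts every ``t0`` iterations."""
    if iteration < 0:
        raise ValueError("iteration must be non-negative")
    t = iteration % cfg.t0
    return cfg.lr_min + 0.5 * (cfg.lr0 - cfg.lr_min) * (1 + math.cos(math.pi * t / cfg.t0))


def _prepare(cohort, window: WindowSpec):
    """Window every volume once and index its lesion-bearing slices."""
    if not cohort:
        raise ValueError("cohort is empty")
    prepped = []
    for vol, mask in cohort:
        win = apply_window(vol, window)
        lesion_slices = np.flatnonzero(mask.labels.reshape(len(win), -1).any(axis=1))
        prepped.append((win, mask.labels, lesion_slices))
    all_vals = np.concatenate([p[0].ravel()[::7] for p in prepped])
    mean, sd = float(all_vals.mean()), float(all_vals.std())
    return prepped, mean, max(sd, 1e-6)


def train(model: MixedUNet, cohort, cfg: TrainConfig = TrainConfig(),
          window: WindowSpec = WindowSpec(), k: int | None = None):
    """Optimise ``model`` in place; returns ``(model, history)``.

    ``history`` records the per-iteration loss and learning rate plus the
    cohort normalisation statistics needed at inference time.
    """
    prepped, mean, sd = _prepare(cohort, window)
    k = k or model.config.in_slices
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr0)
    losses, rates = [], []
    model.train()
    for it in range(cfg.iterations):
        opt.lr = cosine_lr(it, cfg)
        stacks, masks = [], []
        for _ in range(cfg.batch_size):
            win, labels, lesion_slices = prepped[rng.integers(len(prepped))]
            if len(lesion_slices) and rng.random() < cfg.lesion_fraction:
                s = int(lesion_slices[rng.integers(len(lesion_slices))])
            else:
                s = int(rng.integers(len(win)))
            stack = extract_stack(win, s, k)
            m = labels[s]
            if cfg.augment:
                stack, m = augment_rotate(stack, m, rng, cfg.max_rotation_deg)
            stack = normalize_stack(stack, mean, sd)
            stacks.append(stack.slices)
            masks.append(m)
        x = np.stack(stacks)[:, None]                      # (B,1,k,H,W)
        y = np.stack(masks)[:, None].astype(np.float32)    # (B,1,H,W)
        pred = model(x)
        loss = combined_loss(pred, y, cfg.loss)
        if not np.isfinite(loss.data):
            raise RuntimeError(f"non-finite loss at iteration {it}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
        rates.append(opt.lr)
    history = {"loss": losses, "lr": rates, "norm_mean": mean, "norm_sd": sd,
               "iterations": cfg.iterations}
    return model, history


def predict_volume(model, volume, threshold: float = 0.5,
                   window: WindowSpec = WindowSpec(),
                   norm: tuple[float, float] = (0.0, 1.0),
                   batch: int = 8) -> MaskVolume:
    """Slide the stack over every slice and binarize the central-slice maps."""
    win = apply_window(volume, window)
    k = model.config.in_slices if isinstance(model, MixedUNet) else model.in_slices
    mean, sd = norm
    was_training = model.training
    model.eval()
    n = len(win)
    probs = np.empty_like(win, dtype=np.float32)
    for start in range(0, n, batch):
        idxs = range(start, min(start + batch, n))
        stacks = np.stack([
            normalize_stack(extract_stack(win, i, k), mean, sd).slices for i in idxs
        ])
        if isinstance(model, MixedUNet):
            out = model(stacks[:, None])
        else:
            out = model(stacks)
        probs[start:start + len(out.data)] = out.data[:, 0]
    model.train(was_training)
    case_id = getattr(volume, "case_id", "")
    return MaskVolume((probs > threshold).astype(np.uint8), case_id)


def evaluate_cohort(model, cases, seed: int = 0, threshold: float = 0.5,
                    window: WindowSpec = WindowSpec(),
                    norm: tuple[float, float] = (0.0, 1.0)):
    """Per-case metrics plus bootstrap cohort summary.

    Returns ``(frame, summary)`` where ``frame`` is a per-case DataFrame.
    """
    if len(cases) < 2:
        raise ValueError("need at least 2 cases")
    records = []
    for vol, mask in cases:
        pred = predict_volume(model, vol, threshold, window, norm)
        records.append(case_metrics(pred, mask, getattr(vol, "case_id", "")))
    frame = pd.DataFrame([r.to_dict() for r in records])
    summary = aggregate_ci(records, seed)
    return frame, summary


# ---------------------------------------------------------------------------
# model/results facade
# ---------------------------------------------------------------------------

class SegmentationModel:
    """A segmentation experiment bound to a training cohort.

    Mirrors the fit/results convention of statistical modelling packages:
    construct with data and configuration, call :meth:`fit`, and work with
    the returned :class:`SegmentationResults`.
    """

    def __init__(self, cohort, config: MixedNetConfig | None = None,
                 train_config: TrainConfig | None = None,
                 window: WindowSpec | None = None):
        self.cohort = list(cohort)
        self.config = config or MixedNetConfig()
        self.train_config = train_config or TrainConfig()
        self.window = window or WindowSpec()

    def fit(self, seed: int | None = None) -> "SegmentationResults":
        cfg = self.train_config
        if seed is not None:
            cfg = TrainConfig(**{**cfg.__dict__, "seed": seed})
        net = build_mixed_unet(self.config, seed=cfg.seed)
        net, history = train(net, self.cohort, cfg, self.window)
        return SegmentationResults(net, history, cfg, self.window)


class SegmentationResults:
    """Trained network plus everything needed to use and report it."""

    def __init__(self, network: MixedUNet, history: dict, train_config: TrainConfig,
                 window: WindowSpec):
        self.network = network
        self.history = history
        self.train_config = train_config
        self.window = window

    @property
    def norm(self):
        return self.history["norm_mean"], self.history["norm_sd"]

    def predict(self, volume: CTVolume) -> MaskVolume:
        return predict_volume(self.network, volume, self.train_config.threshold,
                              self.window, self.norm)

    def evaluate(self, cases, seed: int = 0):
        return evaluate_cohort(self.network, cases, seed,
                               self.train_config.threshold, self.window, self.norm)

    def summary(self) -> str:
        h = self.history
        head = np.mean(h["loss"][:10]) if h["loss"] else float("nan")
        tail = np.mean(h["loss"][-10:]) if h["loss"] else float("nan")
        cfg = self.network.config
        lines = [
            "Mixed 2D/3D U-Net fit",
            "=" * 42,
            f"parameters            {count_parameters(self.network):>14,}",
            f"input slices (k)      {cfg.in_slices:>14}",
            f"depth trajectory      {'->'.join(map(str, cfg.depth_trajectory())):>14}",
            f"iterations            {h['iterations']:>14}",
            f"loss, first 10 iters  {head:>14.4f}",
            f"loss, last 10 iters   {tail:>14.4f}",
            f"norm mean / sd        {h['norm_mean']:>7.4f}/{h['norm_sd']:.4f}",
        ]
        return "\n".join(lines)
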