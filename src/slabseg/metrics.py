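"""Per-case segmentation metrics and cohort aggregation.

Metrics follow the standard volumetric-overlap definitions: sensitivity
(Sen), specificity (Spe), Dice similarity coefficient, volumetric overlap
error (VOE = 1 - Jaccard), and signed relative volume difference
(RVD = (|pred| - |gt|) / |gt|, positive for over-segmentation).  Sen, Spe,
Dice and VOE are reported as percentages.  Cohort means carry 95%
confidence intervals from a nonparametric bootstrap over cases.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

__all__ = ["CaseMetrics", "CohortSummary", "confusion_counts", "case_metrics",
           "aggregate_ci", "bootstrap_ci", "ssim_pair", "METRIC_NAMES",
           "plot_metric_boxes"]

METRIC_NAMES = ("sen", "spe", "dice", "voe", "rvd")


@dataclass
class CaseMetrics:
    case_id: str
    sen: float
    spe: float
    dice: float
    voe: float
    rvd: float
    defined: bool = True

    def to_dict(self):
        return asdict(self)


@dataclass
class CohortSummary:
    """Per-metric mean and 95% CI bounds over the valid cases."""

    mean: dict
    lower: dict
    upper: dict
    n_cases: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "metric": list(METRIC_NAMES),
            "mean": [self.mean[m] for m in METRIC_NAMES],
            "ci95_lower": [self.lower[m] for m in METRIC_NAMES],
            "ci95_upper": [self.upper[m] for m in METRIC_NAMES],
        })

    def to_json(self, path):
        payload = {"n_cases": self.n_cases}
        for m in METRIC_NAMES:
            payload[m] = {"mean": self.mean[m], "ci95": [self.lower[m], self.upper[m]]}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _binary(arr, name):
    a = np.asarray(getattr(arr, "labels", arr))
    vals = np.unique(a)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary")
    return a.astype(bool)


def confusion_counts(pred, gt):
    """Voxelwise (TP, FP, TN, FN)."""
    p, g = _binary(pred, "pred"), _binary(gt, "gt")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return tp, fp, tn, fn


def case_metrics(pred, gt, case_id: str = "") -> CaseMetrics:
    """All five metrics for one case; percentages are scaled by 100.

    A case with an empty reference mask has no defined Dice/VOE/RVD; it is
    returned with ``defined=False`` and NaN values so aggregation can skip
    it.
    """
    tp, fp, tn, fn = confusion_counts(pred, gt)
    case_id = case_id or getattr(gt, "case_id", "")
    if tp + fn == 0:
        warnings.warn(f"case {case_id!r}: empty reference mask, metrics undefined")
        return CaseMetrics(case_id, np.nan, np.nan, np.nan, np.nan, np.nan, False)
    sen = 100.0 * tp / (tp + fn)
    spe = 100.0 * tn / (tn + fp) if tn + fp else 100.0
    dice = 100.0 * 2 * tp / (2 * tp + fp + fn)
    voe = 100.0 * (1.0 - tp / (tp + fp + fn))
    rvd = ((tp + fp) - (tp + fn)) / (tp + fn)
    return CaseMetrics(case_id, sen, spe, dice, voe, rvd, True)


def bootstrap_ci(values, seed: int, n_boot: int = 2000, level: float = 95.0):
    """Percentile bootstrap CI for the mean of ``values``."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [(100 - level) / 2, 100 - (100 - level) / 2])
    return float(lo), float(hi)


def aggregate_ci(cases, seed: int, n_boot: int = 2000) -> CohortSummary:
    """Cohort mean and bootstrap 95% CI per metric (resampling cases)."""
    valid = [c for c in cases if c.defined]
    if len(valid) < 2:
        raise ValueError("need at least 2 cases with defined metrics")
    mean, lower, upper = {}, {}, {}
    for i, m in enumerate(METRIC_NAMES):
        vals = np.array([getattr(c, m) for c in valid])
        mean[m] = float(vals.mean())
        lower[m], upper[m] = bootstrap_ci(vals, seed + i, n_boot)
    return CohortSummary(mean, lower, upper, len(valid))


def ssim_pair(a, b) -> float:
    """Structural similarity between two windowed slices.

    Gaussian weighting (sigma 1.5, 11x11 support) with the data range of
    windowed intensities, [0, 1].
    """
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("inputs must be two equal-shaped slices")
    return float(structural_similarity(
        a, b, win_size=11, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, data_range=1.0))


def plot_metric_boxes(frame: pd.DataFrame, path):
    """Box plots of Dice, VOE and RVD with mean markers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, m in zip(axes, ("dice", "voe", "rvd")):
        ax.boxplot(frame[m].dropna(), showmeans=True)
        ax.set_title(m.upper() if m != "dice" else "Dice")
        ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
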