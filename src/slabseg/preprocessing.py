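"""HU windowing, slice-stack extraction, normalisation and augmentation.

The display window maps the Hounsfield interval
``[level - width/2, level + width/2]`` linearly onto ``[0, 1]`` and clips
outside it; the soft-tissue window (level 50 HU, width 400 HU) is the
default.  The network input is a stack of ``k`` adjacent windowed slices
centred on the slice to be segmented; positions beyond the first or last
slice are filled by edge replication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import CTVolume

__all__ = ["WindowSpec", "SliceStack", "apply_window", "extract_stack",
           "augment_rotate", "normalize_stack"]


@dataclass
class WindowSpec:
    level: float = 50.0
    width: float = 400.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be positive")


@dataclass
class SliceStack:
    """``k`` adjacent windowed slices; the central one is the prediction target."""

    slices: np.ndarray      # (k, H, W)
    center_index: int       # position of the central slice in the source volume

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=np.float32)
        if self.slices.ndim != 3:
            raise ValueError("stack must be (k, H, W)")
        if self.slices.shape[0] % 2 == 0:
            raise ValueError("stack size k must be odd")

    @property
    def k(self) -> int:
        return self.slices.shape[0]


def apply_window(volume, window: WindowSpec = WindowSpec()) -> np.ndarray:
    """Linear window of HU onto [0, 1], clipped outside."""
    hu = volume.voxels if isinstance(volume, CTVolume) else np.asarray(volume)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU values must be finite")
    lo = window.level - window.width / 2.0
    out = (hu.astype(np.float32) - lo) / window.width
    return np.clip(out, 0.0, 1.0)


def extract_stack(windowed: np.ndarray, center_index: int, k: int = 7) -> SliceStack:
    """Select slices ``center-(k-1)/2 .. center+(k-1)/2`` with edge replication."""
    windowed = np.asarray(windowed)
    if k % 2 == 0 or k < 1:
        raise ValueError("k must be a positive odd number")
    n = windowed.shape[0]
    if not 0 <= center_index < n:
        raise IndexError(f"center {center_index} outside volume of {n} slices")
    half = (k - 1) // 2
    idx = np.clip(np.arange(center_index - half, center_index + half + 1), 0, n - 1)
    return SliceStack(windowed[idx].copy(), center_index)


def augment_rotate(stack: SliceStack, mask_slice: np.ndarray, rng,
                   max_deg: float = 30.0, angle: float | None = None):
    """Rotate every slice of the stack and the paired mask by one shared
    in-plane angle drawn uniformly from [-max_deg, +max_deg].

    Images use bilinear interpolation; the mask uses nearest neighbour and
    is re-binarized, preserving the binary label contract.
    """
    mask_slice = np.asarray(mask_slice)
    if mask_slice.shape != stack.slices.shape[1:]:
        raise ValueError("mask shape does not match stack slices")
    if angle is None:
        angle = float(rng.uniform(-max_deg, max_deg))
    if angle == 0.0:
        return SliceStack(stack.slices.copy(), stack.center_index), mask_slice.copy()
    img = ndimage.rotate(stack.slices, angle, axes=(1, 2), reshape=False,
                         order=1, mode="nearest")
    m = ndimage.rotate(mask_slice.astype(np.float32), angle, reshape=False,
                       order=0, mode="constant", cval=0.0)
    return SliceStack(img, stack.center_index), (m > 0.5).astype(np.uint8)


def normalize_stack(stack: SliceStack, mean: float, sd: float) -> SliceStack:
    """Standardise intensities with cohort statistics."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return SliceStack((stack.slices - mean) / sd, stack.center_index)
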