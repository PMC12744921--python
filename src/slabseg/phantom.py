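"""Synthetic portal-venous liver-CT phantoms with ground-truth lesion masks.

The generator emulates the three properties of contrast-enhanced liver CT
that make lesion segmentation hard: bright, mildly textured parenchyma;
hypodense lesions of variable number, size and shape with irregular
boundaries; and hyperdense tubular vessels that look lesion-like to a
segmenter but are *not* part of the ground-truth mask.  It exists so that
the whole training and evaluation pipeline is exercisable without any
patient data.

Determinism contract: a fixed ``(spec, seed)`` pair reproduces the volume
and mask bit for bit; cohort members get per-case seeds derived from the
master seed through :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "CTVolume", "MaskVolume",
           "generate_phantom", "generate_cohort", "ellipsoid_mask"]


@dataclass
class CTVolume:
    """A rank-3 grid of Hounsfield values, index order (slice, row, col)."""

    voxels: np.ndarray
    spacing: tuple  # mm, (z, y, x)
    case_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("CT volume must be rank 3")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self):
        return self.voxels.shape


@dataclass
class MaskVolume:
    """Binary lesion labels paired with a CT volume.  Vessels are excluded."""

    labels: np.ndarray
    case_id: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("mask must be rank 3")
        vals = np.unique(self.labels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask must be binary (0/1)")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self):
        return self.labels.shape


@dataclass
class PhantomSpec:
    """Generation parameters.  HU palette follows portal-venous contrast:
    lesions hypodense, vessels hyperdense relative to parenchyma."""

    grid_shape: tuple = (16, 96, 96)          # voxels, (D, H, W)
    spacing: tuple = (2.5, 1.5, 1.5)          # mm per axis, (z, y, x)
    parenchyma_hu: tuple = (110.0, 10.0)      # mean, sd
    lesion_count_range: tuple = (1, 3)
    lesion_radius_range: tuple = (6.0, 18.0)  # mm per semi-axis
    lesion_hu: tuple = (55.0, 10.0)
    boundary_perturbation: float = 0.15       # relative radial amplitude
    vessel_count_range: tuple = (2, 4)
    vessel_radius_range: tuple = (1.5, 3.0)   # mm
    vessel_hu: tuple = (150.0, 10.0)
    noise_sd: float = 10.0                    # HU, additive acquisition noise

    def __post_init__(self):
        if any(s < 1 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be three positive integers")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        for name in ("lesion_count_range", "lesion_radius_range",
                     "vessel_count_range", "vessel_radius_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is inverted")
        if self.lesion_count_range[0] < 0:
            raise ValueError("lesion count cannot be negative")
        if not (self.lesion_hu[0] < self.parenchyma_hu[0] < self.vessel_hu[0]):
            raise ValueError(
                "HU ordering violated: need lesion < parenchyma < vessel")
        if self.boundary_perturbation < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    """Boolean voxelization of an axis-aligned ellipsoid (voxel units)."""
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    q = (((zz - center[0]) / semiaxes[0]) ** 2
         + ((yy - center[1]) / semiaxes[1]) ** 2
         + ((xx - center[2]) / semiaxes[2]) ** 2)
    return q <= 1.0


def _smooth_field(rng, shape, sigma) -> np.ndarray:
    """Unit-variance smooth noise used for texture and boundary jitter."""
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _draw_lesion(rng, spec: PhantomSpec, noise_field: np.ndarray) -> np.ndarray:
    D, H, W = spec.grid_shape
    sz, sy, sx = spec.spacing
    r_lo, r_hi = spec.lesion_radius_range
    ax_mm = rng.uniform(r_lo, r_hi, size=3)          # semi-axes in mm
    ax_vox = ax_mm / np.array([sz, sy, sx])
    center = [rng.uniform(min(a + 1, s / 2), max(s - a - 1, s / 2))
              for a, s in zip(ax_vox, (D, H, W))]
    zz, yy, xx = np.ogrid[:D, :H, :W]
    q = (((zz - center[0]) / ax_vox[0]) ** 2
         + ((yy - center[1]) / ax_vox[1]) ** 2
         + ((xx - center[2]) / ax_vox[2]) ** 2)
    r = np.sqrt(q)
    # radial perturbation of the surface -> irregular boundary
    return r <= 1.0 + spec.boundary_perturbation * noise_field


def _draw_vessel(rng, spec: PhantomSpec) -> np.ndarray:
    """A random-walk tube stamped as spheres along its path."""
    D, H, W = spec.grid_shape
    sz, sy, sx = spec.spacing
    radius_mm = rng.uniform(*spec.vessel_radius_range)
    pos = np.array([rng.uniform(0, D), rng.uniform(0, H), rng.uniform(0, W)])
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    mask = np.zeros((D, H, W), dtype=bool)
    rz, ry, rx = max(radius_mm / sz, 0.6), radius_mm / sy, radius_mm / sx
    n_steps = int(2.5 * max(D, H, W))
    for _ in range(n_steps):
        z, y, x = pos
        if 0 <= z < D and 0 <= y < H and 0 <= x < W:
            z0, z1 = int(max(z - rz - 1, 0)), int(min(z + rz + 2, D))
            y0, y1 = int(max(y - ry - 1, 0)), int(min(y + ry + 2, H))
            x0, x1 = int(max(x - rx - 1, 0)), int(min(x + rx + 2, W))
            zz, yy, xx = np.ogrid[z0:z1, y0:y1, x0:x1]
            q = (((zz - z) / rz) ** 2 + ((yy - y) / ry) ** 2 + ((xx - x) / rx) ** 2)
            mask[z0:z1, y0:y1, x0:x1] |= q <= 1.0
        direction += 0.35 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = pos + direction * np.array([0.5, 1.2, 1.2])
    return mask


def generate_phantom(spec: PhantomSpec, seed: int, return_vessels: bool = False):
    """Generate one (CTVolume, MaskVolume) pair.

    With ``return_vessels=True`` a third boolean array marks the vessel
    distractor voxels (useful for validating that they are excluded from
    the lesion mask).
    """
    if not isinstance(spec, PhantomSpec):
        raise TypeError("spec must be a PhantomSpec")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    D, H, W = spec.grid_shape

    hu = np.full((D, H, W), spec.parenchyma_hu[0], dtype=np.float32)
    hu += (spec.parenchyma_hu[1] * _smooth_field(rng, (D, H, W), 4.0)).astype(np.float32)

    lesion_mask = np.zeros((D, H, W), dtype=bool)
    n_lesions = int(rng.integers(spec.lesion_count_range[0],
                                 spec.lesion_count_range[1] + 1))
    boundary_noise = _smooth_field(rng, (D, H, W), 3.0)
    lesion_values = np.zeros((D, H, W), dtype=np.float32)
    for _ in range(n_lesions):
        les = _draw_lesion(rng, spec, boundary_noise)
        level = rng.normal(spec.lesion_hu[0], spec.lesion_hu[1] / 2)
        lesion_values[les] = level
        lesion_mask |= les
    hu[lesion_mask] = lesion_values[lesion_mask]

    vessel_mask = np.zeros((D, H, W), dtype=bool)
    n_vessels = int(rng.integers(spec.vessel_count_range[0],
                                 spec.vessel_count_range[1] + 1))
    for _ in range(n_vessels):
        vessel_mask |= _draw_vessel(rng, spec)
    vessel_mask &= ~lesion_mask      # distractors never overlap the label
    if vessel_mask.any():
        hu[vessel_mask] = rng.normal(spec.vessel_hu[0], spec.vessel_hu[1] / 2)

    if spec.noise_sd > 0:
        hu += rng.normal(0, spec.noise_sd, size=(D, H, W)).astype(np.float32)

    case_id = f"phantom-{seed}"
    vol = CTVolume(hu, spec.spacing, case_id)
    mask = MaskVolume(lesion_mask.astype(np.uint8), case_id)
    if return_vessels:
        return vol, mask, vessel_mask
    return vol, mask


def generate_cohort(n_cases: int, spec: PhantomSpec, seed: int):
    """Generate a list of distinct cases with per-case seeds derived from
    the master seed."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_cases)
    out = []
    for i, child in enumerate(children):
        case_seed = int(child.generate_state(1)[0] % (2 ** 31))
        vol, mask = generate_phantom(spec, case_seed)
        vol.case_id = mask.case_id = f"phantom-{seed}-{i:03d}"
        out.append((vol, mask))
    return out
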