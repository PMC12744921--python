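"""NIfTI readers/writers, YAML configuration and run manifests.

Volumes are stored as signed 16-bit HU, masks as unsigned 8-bit.  In
memory the array order is (slice, row, col); on disk the axes are
transposed to the conventional (x, y, z) order with voxel spacing carried
in the affine.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .phantom import CTVolume, MaskVolume, PhantomSpec

__all__ = ["read_volume", "read_mask", "write_volume", "write_mask",
           "write_phantom_case", "read_cases", "load_yaml", "write_manifest"]


def _affine(spacing):
    sz, sy, sx = spacing
    return np.diag([sx, sy, sz, 1.0])


def read_volume(path) -> CTVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).T.astype(np.float32)  # (z, y, x)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return CTVolume(data, spacing, Path(path).name.split(".")[0])


def read_mask(path) -> MaskVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).T
    return MaskVolume(data.astype(np.uint8), Path(path).name.split(".")[0])


def write_volume(volume: CTVolume, path):
    arr = np.round(volume.voxels).astype(np.int16).T
    nib.save(nib.Nifti1Image(arr, _affine(volume.spacing)), str(path))


def write_mask(mask: MaskVolume, path, reference: CTVolume):
    labels = np.asarray(mask.labels)
    if not np.all(np.isin(np.unique(labels), (0, 1))):
        raise ValueError("mask must be binary")
    if labels.shape != reference.shape:
        raise ValueError("mask shape does not match reference volume")
    arr = labels.astype(np.uint8).T
    nib.save(nib.Nifti1Image(arr, _affine(reference.spacing)), str(path))


def write_phantom_case(volume: CTVolume, mask: MaskVolume, out_dir,
                       spec: PhantomSpec, seed: int):
    """Volume + mask + JSON sidecar recording the generating spec and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cid = volume.case_id or "case"
    write_volume(volume, out / f"{cid}_ct.nii.gz")
    write_mask(mask, out / f"{cid}_mask.nii.gz", volume)
    with open(out / f"{cid}.json", "w") as fh:
        json.dump({"case_id": cid, "seed": seed, "spec": spec.to_dict()}, fh, indent=2)


def read_cases(data_dir):
    """Load all ``*_ct.nii.gz`` / ``*_mask.nii.gz`` pairs from a directory."""
    data_dir = Path(data_dir)
    cases = []
    for ct_path in sorted(data_dir.glob("*_ct.nii.gz")):
        mask_path = data_dir / ct_path.name.replace("_ct.", "_mask.")
        if not mask_path.exists():
            raise FileNotFoundError(f"no mask for {ct_path.name}")
        vol = read_volume(ct_path)
        mask = read_mask(mask_path)
        cid = ct_path.name[:-len("_ct.nii.gz")]
        vol.case_id = mask.case_id = cid
        cases.append((vol, mask))
    if not cases:
        raise FileNotFoundError(f"no cases found in {data_dir}")
    return cases


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_manifest(out_dir, config: dict, seed: int, extra: dict | None = None):
    """Record enough to reproduce a run: config hash, seed, package version."""
    from . import __version__
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
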