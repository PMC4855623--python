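"""NIfTI-1 and sidecar I/O helpers.

Volumes are written uncompressed (.nii) in RAS+ with the voxel size on the
affine diagonal, so byte-identical inputs produce byte-identical files and
run manifests of checksums are reproducible. Coordinates are voxel-space
throughout; no registration or resampling is performed anywhere in the
package.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_volume", "load_volume", "save_json", "load_json", "sha256_of"]


def save_volume(path: str | Path, data: np.ndarray, voxel_size_mm: float = 1.0) -> Path:
    path = Path(path)
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    voxel = float(img.header.get_zooms()[0])
    return data, voxel


def save_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
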