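"""File formats: NIfTI voxel maps, dense matrix containers, cohort CSV.

Voxel maps live in NIfTI-1 volumes; in-mask voxels are linearised in a
stable order with the first axis fastest-varying, matching
:class:`subgrad.simulate.Geometry`.  Dense runtime matrices (time series,
FC) are stored as ``.npy`` with a JSON sidecar describing shape and
semantics, which round-trips losslessly and stays language-agnostic.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from subgrad.simulate import Geometry


def write_voxel_map(
    values: np.ndarray, geometry: Geometry, path, mask: np.ndarray | None = None
) -> None:
    """Write a per-voxel vector into a NIfTI-1 volume on the lattice grid."""
    values = np.asarray(values, dtype=np.float32)
    vol = np.zeros(geometry.shape, dtype=np.float32, order="F")
    flat = vol.ravel(order="F")
    if mask is None:
        flat[:] = values
    else:
        flat[np.asarray(mask, bool)] = values
    nib.save(nib.Nifti1Image(vol, geometry.affine), str(path))


def write_mask(geometry: Geometry, path) -> None:
    vol = np.ones(geometry.shape, dtype=np.uint8)
    nib.save(nib.Nifti1Image(vol, geometry.affine), str(path))


def read_voxel_maps(path, mask_path) -> np.ndarray:
    """Read in-mask voxel values in first-axis-fastest order.

    The data and mask grids must agree in shape and affine; a mismatch
    raises with both affines printed.
    """
    img = nib.load(str(path))
    mask_img = nib.load(str(mask_path))
    if img.shape[:3] != mask_img.shape[:3]:
        raise ValueError(
            f"grid mismatch: data {img.shape[:3]} vs mask {mask_img.shape[:3]}"
        )
    if not np.allclose(img.affine, mask_img.affine, atol=1e-6):
        raise ValueError(
            "affine mismatch between data and mask:\n"
            f"data affine:\n{img.affine}\nmask affine:\n{mask_img.affine}"
        )
    mask = np.asanyarray(mask_img.dataobj) > 0
    if not mask.any():
        raise ValueError("mask contains no voxels")
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        return _extract(data, mask)
    # 4-D: subjects / components along the 4th axis
    return np.stack([_extract(data[..., i], mask) for i in range(data.shape[3])])


def _extract(vol: np.ndarray, mask: np.ndarray) -> np.ndarray:
    flat = np.asarray(vol).ravel(order="F")
    mflat = np.asarray(mask).ravel(order="F")
    return flat[mflat].astype(float)


def save_matrix(array: np.ndarray, path, **meta) -> None:
    """Dense matrix container: ``.npy`` plus a JSON sidecar."""
    path = Path(path)
    np.save(path, np.asarray(array))
    sidecar = {"shape": list(np.asarray(array).shape), **meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_matrix(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    arr = np.load(path)
    sidecar_path = path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return arr, meta
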